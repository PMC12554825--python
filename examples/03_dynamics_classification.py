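"""Detect the dynamics of a progressing disease from the ratio-K trajectory.

Four synthetic models generate 10 symmetric 4x4 matrices each: null (fresh
random entries every step), increasing, decreasing, and varying
(rise-then-fall).  The step-wise ratio operator K(t) = G(t+1)/G(t) occupies
a characteristic band per model — above 1 when entries grow, inside (0, 1)
when they shrink — which is enough to classify the generating dynamics.
"""

from koperator import classify_dynamics, evolve_k, fit_quadratic, simulate_model

for model in ("null", "increasing", "decreasing", "varying"):
    series = simulate_model(model, n=4, steps=10, delta_range=(0.01, 0.05), seed=7)
    traj = evolve_k(series)
    lo, hi = traj.element_range
    label = classify_dynamics(traj)
    print(f"{model:>10}: K elements in [{lo:7.3f}, {hi:7.3f}] -> classified {label!r}")

# per-element trend of the increasing model, as a quadratic in time
series = simulate_model("increasing", seed=7)
fit = fit_quadratic(series)
a, b, c = fit.element(0, 1)
print(f"\nelement (0,1) quadratic trend: G(t) = {a:.4f} t^2 + {b:.4f} t + {c:.4f}, "
      f"residual SSE = {fit.residual_sse[0, 1]:.4f}")
print("The increasing/decreasing bands sit strictly above/below K = 1; the "
      "null model respects no band and falls through to 'null' only when the "
      "heavy-tailed step-means leave the other patterns.")
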