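"""Fit candidate distributions to an inter-departure-time sample.

Draws 5,000 intervals from a Gamma distribution with shape 3 and scale
15 (a dispersed, hypoexponential train: CV = 3**-0.5 = 0.577), fits
Gamma, Weibull and Normal models by maximum likelihood, and ranks them
by the chi-square statistic on equiprobable bins.  The Gamma fit should
recover the generating parameters and win the ranking.
"""

from neurotraffic import fit_candidates, rank_fits
from neurotraffic.synth import generate_gamma_sample

sample = generate_gamma_sample(shape=3.0, scale=15.0, n=5_000, seed=7)
fits = fit_candidates(sample, ("gamma", "weibull", "normal"))
ranked = rank_fits(sample, fits)

print("rank  distribution  chi2        df   params")
for i, (fit, gof) in enumerate(ranked, 1):
    params = ", ".join(f"{p:.3f}" for p in fit.params)
    print(f"{i:4d}  {fit.name:12s} {gof.statistic:9.1f} {gof.degrees_of_freedom:4d}"
          f"   ({params})")

best = ranked[0][0]
print(f"\nBest fit: {best.name} with shape {best.params[0]:.3f} and scale "
      f"{best.params[1]:.2f};")
print(f"its coefficient of variation shape**-0.5 = {best.params[0]**-0.5:.3f} < 1")
print("marks the sample as hypoexponential (serial-stage-like).")
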