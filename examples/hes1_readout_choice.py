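"""Which Hes1 readout to measure: mRNA (qPCR) or total protein (Western)?

Two routes to the answer:

1. nested Monte-Carlo estimates of the per-parameter mutual information for
   each readout, at matched seeds (the method's own criterion) — noisy at
   small sample sizes;
2. a cheap low-noise oracle: the average squared sensitivity of the readout
   to each parameter over prior draws, on a log scale — stable, and a good
   sanity check on the MI route.

Under the package default of *equal* measurement variance for both
readouts, the two readouts are close: protein is at least as informative
for the threshold, Hill coefficient and transport rate, while mRNA clearly
wins only for the translation rate.
"""

import numpy as np

import infodesign as idn
from infodesign.mi import estimate_mi_component

model, (e_mrna, e_protein) = idn.build_hes1()
prior = idn.hes1_prior()
sigma2 = float(e_mrna.noise_variance["mRNA"])

# --- route 1: matched-seed MI estimates ------------------------------------
print(f"{'parameter':>10} {'I(.;mRNA)':>12} {'I(.;protein)':>14}   (nats, matched seeds)")
for pname in model.parameter_names:
    em = estimate_mi_component(pname, model, e_mrna, prior,
                               N=60, K=150, M=150, R=2, seed=5)
    ep = estimate_mi_component(pname, model, e_protein, prior,
                               N=60, K=150, M=150, R=2, seed=5)
    print(f"{pname:>10} {em.value:12.2f} {ep.value:14.2f}")

# --- route 2: average-sensitivity oracle ------------------------------------
rng = np.random.default_rng(0)
thetas = prior.sample(150, rng)


def mean_log_sensitivity(exp):
    out = np.zeros(model.n_parameters)
    for th in thetas:
        for i in range(model.n_parameters):
            h = 1e-4 * abs(th[i])
            up, dn = th.copy(), th.copy()
            up[i] += h
            dn[i] -= h
            d = (idn.integrate(model, up, exp).values
                 - idn.integrate(model, dn, exp).values).ravel() / (2 * h)
            out[i] += 0.5 * np.log1p(np.sum(d ** 2) / sigma2)
    return out / len(thetas)


sm = mean_log_sensitivity(e_mrna)
sp = mean_log_sensitivity(e_protein)
print(f"\n{'parameter':>10} {'sens(mRNA)':>12} {'sens(protein)':>14}   (mean 0.5*log(1+S/s2))")
for i, pname in enumerate(model.parameter_names):
    marker = "  <- mRNA" if sm[i] > sp[i] else "  <- protein"
    print(f"{pname:>10} {sm[i]:12.2f} {sp[i]:14.2f}{marker}")

print("\nThe MI column is the design criterion itself but carries large"
      "\nMonte-Carlo error at these sizes; the sensitivity column is the"
      "\nstable low-noise ordering. With equal readout noise the protein"
      "\nreadout holds its own except for the translation rate nu.")
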