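"""Simulate one data set with multi-hit substitutions and compare models.

Generates a 15-taxon, 150-codon alignment under the scheme-B generator
(~11% double/triple substitution events), then fits M0 (single-hit, 2
parameters) and two KCM variants and ranks them by AICc.  A positive
delta AICc means the variant beats M0 after the parameter penalty.
"""

import numpy as np

from kcm import (build_scheme_matrix, delta_aicc, fit, random_tree,
                 simulate_alignment)

rng = np.random.default_rng(7)
tree = random_tree(15, rng=rng)
Q = build_scheme_matrix("B", omega_factor=1.0, rng=rng)
aln = simulate_alignment(tree, Q, 150, rng=rng)
print(f"simulated: {aln.n_taxa} taxa x {aln.n_sites} codons, "
      f"tree length {tree.total_length:.1f} substitutions/codon\n")

fits = {name: fit(aln, tree, name, seed=1, n_starts=1)
        for name in ("M0", "KCM7x", "KCM19x")}

print(f"{'model':<8} {'lnL':>10} {'k':>3} {'AICc':>10} {'dAICc':>8} {'omega':>7}")
for name, f in fits.items():
    d = delta_aicc(fits["M0"], f) if name != "M0" else 0.0
    print(f"{name:<8} {f.lnL:>10.2f} {f.spec.k_free:>3} {f.aicc:>10.2f} "
          f"{d:>8.2f} {f.omega:>7.3f}")
print()
print("With real multi-hit events in the data the alpha=1 variants gain far")
print("more log-likelihood than their extra parameters cost, so their delta")
print("AICc versus M0 is strongly positive.")
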