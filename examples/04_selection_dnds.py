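"""Trinucleotide-context Poisson dN/dS selection inference.

Builds random gene models, plants strong positive selection (omega = 10)
on a third of them, draws a mutation catalog under the Poisson model, and
estimates the set-level dN/dS ratios and driver fractions.
"""

import numpy as np

from glandevo import (
    estimate_context_rates,
    gene_set_dnds,
)
from glandevo.synthetic import (
    random_gene_model,
    simulate_noncoding_catalog,
    simulate_selection_catalog,
)

models = {f"G{i + 1}": random_gene_model(f"G{i + 1}", 300, seed=i)
          for i in range(9)}
selected = ["G1", "G2", "G3"]

noncoding = simulate_noncoding_catalog([0.3, 0.7], 1_000_000, seed=0)
rates = estimate_context_rates(noncoding, models.values(), observed_total=1.0)
catalog = simulate_selection_catalog(
    models, {g: 10.0 for g in selected}, t=1.5e-2, r=rates.r, seed=0)
total = float(catalog[["missense", "nonsense", "synonymous"]].to_numpy().sum())
rates = estimate_context_rates(noncoding, models.values(), observed_total=total)

for name, genes in (("selected", selected),
                    ("neutral", [g for g in models if g not in selected])):
    fit = gene_set_dnds(catalog, rates, models, name, genes)
    m = fit.missense
    print(f"{name:>8}: omega_missense = {m.omega:5.2f} "
          f"(95% CI {m.ci_low:.2f}-{m.ci_high:.2f}, p = {m.p:.1e}); "
          f"driver fraction = {100 * fit.driver_fraction_missense:.1f}%")
# The selected set recovers omega ~10 (planted), meaning ~90% of its
# observed missense mutations are genuine drivers; the neutral set sits
# at omega ~1 with driver fraction 0.
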