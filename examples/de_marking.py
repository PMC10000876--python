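"""Filter simulated RNA-seq counts with the three-part DE-marking rule and
test a gene category for enrichment with Fisher's exact test.

A gene is marked differentially expressed when it has at least 10 counts in
at least half the samples of one group, p <= 0.05 and |log2 fold change|
>= 0.5. The p values here come from a t test on log counts; in a real
analysis they would come from a count-model fit.
"""

import numpy as np
from scipy import stats

from odontomorph.crownstats import fisher_enrichment, mark_de_genes
from odontomorph.simulate import simulate_counts

counts, labels, truth = simulate_counts(
    n_genes=2000, n_per_group=6, nb_mean=100.0, nb_dispersion=0.1,
    de_fraction=0.1, log2fc=2.0, seed=1)

log_counts = np.log2(counts.to_numpy() + 1.0)
groups = np.asarray(labels)
a, b = log_counts[:, groups == "A"], log_counts[:, groups == "B"]
frame = counts.copy()
frame["p_value"] = stats.ttest_ind(a, b, axis=1).pvalue
frame["log2fc"] = b.mean(axis=1) - a.mean(axis=1)

flagged = mark_de_genes(frame, labels, count_columns=list(counts.columns))
n_flag = int(flagged["de_flag"].sum())
recovered = float(flagged["de_flag"].to_numpy()[truth].mean())
print(f"genes marked DE: {n_flag}/{len(flagged)}")
print(f"spiked genes recovered: {100 * recovered:.1f}%")

# enrichment of the spiked subset among the flagged genes
flags = flagged["de_flag"].to_numpy()
p = fisher_enrichment(int((flags & truth).sum()), int((flags & ~truth).sum()),
                      int((~flags & truth).sum()), int((~flags & ~truth).sum()))
print(f"Fisher exact enrichment p = {p:.3e}")
# Near-complete recovery with a tiny enrichment p shows the marking rule
# isolates the genes whose group means truly differ.
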