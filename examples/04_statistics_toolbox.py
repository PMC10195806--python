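"""The small statistics used throughout: worked closed-form examples.

Prints the Monte-Carlo chi-squared test on a hand-checkable 2x2 table,
the Benjamini-Hochberg step-up adjustment, a Welch t-test with
Satterthwaite degrees of freedom, a normalised competitive co-culture
ratio, and the CDS-position -> codon mapping used to annotate a coding
variant.
"""

import metscreen as ms

res = ms.chisq_test([[10, 20], [20, 10]])
mc = ms.chisq_test([[10, 20], [20, 10]], simulate=True, n_replicates=2000, seed=0)
print(f"Pearson statistic {res.statistic:.4f} (sum of (O-E)^2/E, all E = 15)")
print(f"asymptotic p = {res.p_value:.4g}; simulated p (2000 tables, fixed margins) = {mc.p_value:.4g}")

print(f"\nBH on (0.01, 0.02, 0.04) -> {[float(q) for q in ms.bh_adjust([0.01, 0.02, 0.04]).round(4)]}")

w = ms.welch_t([1, 2, 3], [2, 3, 4])
print(f"Welch t = {w.statistic:.4f}, Satterthwaite df = {w.df:.1f}, p = {w.p_value:.4f}")

ratio = ms.competitive_ratio([100, 50, 25], [100, 100, 100], [1.0, 1.0, 1.0])
print(f"\ncompetitive ratio, channel A halving per timepoint: {[float(r) for r in ratio]}")

codon, pos = ms.codon_of_cds_position(1939)
print(f"\nCDS position 1939 -> codon {codon}, position {pos} in codon")
print("(the acquired receptor variant c.1939C>T changes codon 647, Pro -> Ser)")
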