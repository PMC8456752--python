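"""Balance a confounded cohort so no covariate separates the classes.

The balancer discretizes each covariate into equal-width bins, matches
subjects across classes within every multivariate bin, and refines the bin
count of the worst covariate until every two-sided Mann-Whitney p exceeds
.10 on the retained subset. With the forced 1:1 option the retained classes
are exactly equal in size.
"""

from scipy.stats import mannwhitneyu

import connectoscramble as cs

spec = cs.CohortSpec(n_subjects=2000, seed=3)
table = cs.generate_phenotypes(spec)

config = cs.BalanceConfig(seed=0)              # forced 1:1, p > .10
kept, cert = cs.balance(table, config, "sex")
sub = table.loc[kept]

print(f"input: {len(table)} subjects; retained: {len(sub)} "
      f"({(sub.sex == 1).sum()} male / {(sub.sex == 0).sum()} female)")
print(f"final bin counts: {cert.bin_counts}")
print("\ncovariate      p before     p after (certificate / recomputed)")
for cov in config.covariates:
    before = mannwhitneyu(table[table.sex == 0][cov], table[table.sex == 1][cov],
                          alternative="two-sided").pvalue
    after = mannwhitneyu(sub[sub.sex == 0][cov], sub[sub.sex == 1][cov],
                         alternative="two-sided").pvalue
    print(f"  {cov:<10}  {before:10.2e}   {cert.p_values[cov]:.3f} / {after:.3f}")
print("\nICV separates the sexes decisively before balancing and is "
      "statistically indistinguishable afterwards; every retained male has "
      "covariate-matched female counterparts.")
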