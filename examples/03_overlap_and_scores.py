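"""Venn-style overlap percentages and the enrichment-score comparison.

The published-style arithmetic: with 894 miR-133a targets of which 270 are
m6A-modified, 30.20% of targets carry the mark; the miR-499 analogue
(102/416) gives 24.52%. On synthetic scores, m6A-modified targets drawn with
a +1 shift separate clearly under the pooled two-sample t test.
"""

import numpy as np

from m6amir import compare_scores, overlap

targets = {f"t{i}" for i in range(894)}
m6a_modified = {f"t{i}" for i in range(270)} | {f"m{i}" for i in range(2548)}
s = overlap(targets, m6a_modified, "miR-133a targets", "m6A-modified genes")
print(f"{s.set_a_name} vs {s.set_b_name}: {s.n_intersection}/{s.n_a} "
      f"= {s.pct_rendered}% of targets are m6A-modified")

rng = np.random.default_rng(0)
with_m6a = rng.normal(3.0, 1.0, 60)     # enrichment scores, m6A-modified targets
without_m6a = rng.normal(2.0, 1.0, 140)  # unmodified targets
r = compare_scores(with_m6a, without_m6a)
print(f"t = {r.t_stat:.2f} (df = {r.df:.0f}), two-sided p = {r.p_two_sided:.2e}")
# A positive t with small p: modified targets have higher AGO2 enrichment.
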