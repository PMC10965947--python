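"""Slide-level TPS agreement battery on a simulated 6-reader panel.

Simulates visual TPS estimates (Gaussian reader noise, clipped to [0,100],
rounded to 5% increments) for 100 cases, then computes ICC(2,1), linear
weighted kappa over the clinical categories (<1%, 1-49%, >=50%), kappas at
the 1% and 50% cutoffs, majority-vote agreement and Bland-Altman limits.
"""

from itertools import combinations

import numpy as np

from pdl1bench import (
    bland_altman,
    discretize_tps,
    icc_2_1,
    kappa_at_cutoff,
    linear_kappa,
    majority_vote_agreement,
    simulate_tps_panel,
)

rng = np.random.default_rng(3)
true_tps = np.clip(rng.uniform(-10, 110, 100), 0, 100)  # spans all three bands
panel = simulate_tps_panel(true_tps, n_readers=6, reader_sd_pct=8.0, seed=4)
table = panel.estimates

icc = icc_2_1(table)
print(f"ICC(2,1) over 6 readers: {icc.value:.3f} (95% CI {icc.ci_low:.3f}-{icc.ci_high:.3f})")

codes = {r: [discretize_tps(v) for v in table[r]] for r in table.columns}
kappas = [linear_kappa(codes[a], codes[b]) for a, b in combinations(table.columns, 2)]
print(f"mean pairwise linear kappa (3 clinical categories): {np.mean(kappas):.3f}")

for cutoff in (1.0, 50.0):
    k = [kappa_at_cutoff(table[a], table[b], cutoff) for a, b in combinations(table.columns, 2)]
    mv = majority_vote_agreement(table, table.columns[0], cutoff)
    print(f"cutoff {cutoff:>4.0f}%: mean pairwise kappa {np.nanmean(k):.3f}, "
          f"reader {table.columns[0]} vs majority {mv.kappa:.3f} ({mv.n_ties} ties dropped)")

ba = bland_altman(table.iloc[:, 0], table.median(axis=1))
print(f"Bland-Altman {table.columns[0]} vs median reader: "
      f"mean diff {ba.mean_diff:+.2f}, limits [{ba.loa_low:.2f}, {ba.loa_high:.2f}]")
print("\nKappa near 0.5-0.7 with ICC near 0.95 is typical: continuous agreement is")
print("high while category agreement suffers near the 1% and 50% decision boundaries.")
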