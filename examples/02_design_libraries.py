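"""Rank clusters by significance and design probe libraries.

From a clustered synthetic selection: binomial-tail significance ranking,
then the SYM (top representatives), NG1 (weakest members), NGR
(anti-selected negatives) and RND (random) libraries.
"""

from igomeprof.composition import estimate_background
from igomeprof.gibbs import GibbsParams, gibbs_cluster
from igomeprof.library_design import (
    cluster_significance,
    design_ng,
    design_ngr,
    design_rnd,
    design_sym,
)
from igomeprof.synthetic import SelectionConfig, simulate_selection

cfg = SelectionConfig(K=4, peptides_per_cluster=30, background_fraction=0.0,
                      error_rate=0.0, motif_weight=0.9)
_, truth = simulate_selection(cfg, seed=11)
state = gibbs_cluster(truth.peptides, 4, GibbsParams(iters=40, restarts=2), seed=11)

bg = estimate_background("nnk")  # display-library NNK codon frequencies
signif = cluster_significance(state, bg, M=10_000, seed=11)
print("cluster significance (rank, cluster, members, binomial p):")
for r in signif:
    print(f"  #{r.rank}  cluster {r.cluster}  n={r.n_members}  p={r.p:.2e}"
          f"  {'significant' if r.significant else 'ns'}")

n_sig = sum(r.significant for r in signif)
sym = design_sym(state, signif, k_top=n_sig)
ng1, ng2 = design_ng(state, signif)
ngr = design_ngr(state, bg, n_candidates=100_000, m=50, seed=11)
rnd = design_rnd(bg, n=50, seed=11)

print(f"\nSYM: {len(sym)} representatives, mean PWM score "
      f"{sym.provenance['score'].mean():.1f} bits")
print(f"NG1: {len(ng1)} weakest members; NG2 (margin < 5): {len(ng2)}")
print(f"NGR: {len(ngr)} anti-selected, mean max-score "
      f"{ngr.provenance['score'].mean():.1f} bits (deeply negative = unlike "
      f"every cluster profile)")
print(f"RND: {len(rnd)} background draws")
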