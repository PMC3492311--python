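"""Sequencing-design arithmetic for a pooled screen.

21 specimens, ~10 surviving clones each, ~7 integrated inserts per clone
averaging 2 kb: how deeply does 10^10 sequenced bases cover the pooled
cDNA?
"""

from attbdeconv import plan_coverage

plan = plan_coverage(
    n_specimens=21,
    clones_per_specimen=10,
    inserts_per_clone=7,
    mean_insert_bp=2000,
    sequenced_bp=1e10,
)
print(f"total cDNA        : {plan.total_cdna_bp:,.0f} bp")
print(f"mean fold coverage: {plan.fold_coverage:,.0f}x")
# ~2.94 Mb of cDNA at >3000-fold: deep enough to recover long or
# inefficiently amplified inserts.
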