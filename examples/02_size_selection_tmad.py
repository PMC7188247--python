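"""Show how in-silico size selection rescues ctDNA detection.

Simulates a low-tumor-fraction sample (tf = 0.03, c=4 gains over ~30% of
the genome, 2M fragments) and compares the tMAD detection statistic with
and without restricting fragments to the 90-150 bp window. Tumor-derived
fragments are shorter (mode 145 bp vs 167 bp), so the window enriches the
tumor fraction several-fold; the size-selected arm's tMAD rises above the
0.015 threshold while the unselected arm stays silent — the behavior that
makes size selection worthwhile at low ctDNA burden.
"""

import fragmad as fm

bins = fm.make_bins(n_bins=56, bin_size=1_000_000, seed=3)
segments = [
    ((0, 5), 2), ((5, 10), 4), ((10, 22), 2), ((22, 27), 4),
    ((27, 39), 2), ((39, 44), 4), ((44, 56), 2),
]
truth = fm.make_truth(bins, segments, tf=0.03)
fragments = fm.simulate_fragments(truth, bins, n_fragments=2_000_000, seed=3)

report = fm.compare_pipelines(
    fragments.drop(columns=["origin"]), bins, min_fragments=2_000_000
)

tumor_share = (fragments["origin"] == "tumor").mean()
selected = fm.size_select(fragments)
print(f"tumor-origin share before selection: {tumor_share:.3f}")
print(f"tumor-origin share after selection:  {(selected['origin'] == 'tumor').mean():.3f}")
for label, arm in (("unselected", report.unselected), ("size-selected", report.selected)):
    flag = "ctDNA DETECTED" if arm.tmad.detected else "not detected"
    print(
        f"{label:>14}: {arm.n_fragments:>9} fragments, "
        f"tMAD = {arm.tmad.value:.4f} (threshold 0.015) -> {flag}"
    )
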