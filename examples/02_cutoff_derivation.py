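"""Derive extreme-centile cut-offs empirically from a cohort.

Bins each marker's centiles into 5-point bins per karyotype group,
computes the abnormal/normal percentage-frequency ratio per bin, and
selects the maximum-ratio bin as the cut-off.
"""

from tetradscreen import Marker, Karyotype, bin_centiles, derive_cutoff, fixture_cohort
from tetradscreen.biometry import default_curves
from tetradscreen.cutoffs import N_BINS, frequency_ratio
from tetradscreen.pipeline import cohort_centiles

records = fixture_cohort()
cent = cohort_centiles(records, default_curves())
abn = [r.karyotype is Karyotype.ABNORMAL for r in records]

for mk in (Marker.GSMD, Marker.YSMD, Marker.CRL):
    col = f"{mk.value.lower()}_centile"
    hist = bin_centiles(
        mk,
        cent.loc[[not a for a in abn], col],
        cent.loc[abn, col],
    )
    spec = derive_cutoff(hist)
    arrow = "<" if spec.direction == "below" else ">="
    print(f"{mk.value}: cut-off {arrow} {spec.threshold:g}th centile "
          f"(winning frequency ratio {spec.ratio:.2f})")
    # show the two extreme bins' ratios for context
    for i in (0, N_BINS - 1):
        r = frequency_ratio(hist, i)
        lo, hi = hist.bin_edges[i], hist.bin_edges[i + 1]
        print(f"   bin [{lo},{hi}): abnormal {hist.counts_abnormal[i]}/{hist.n_abnormal}, "
              f"normal {hist.counts_normal[i]}/{hist.n_normal}, ratio {r:.2f}")

# A ratio > 1 marks a bin over-represented among abnormal karyotypes; the
# extreme bins dominate, recovering the preselected < 5th / >= 95th rules.
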