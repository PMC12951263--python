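"""Date a pregnancy and convert crude biometry to gestation-adjusted centiles.

Builds one scan's measurements, ages them against three dating anchors,
and prints each marker's centile under the packaged reference curves.
"""

import datetime as dt

from tetradscreen import (
    DatingInfo, DatingMethod, Marker, Measurement, default_curves, ga_days, to_centile,
)

scan = dt.date(2023, 3, 11)
dating = DatingInfo(DatingMethod.LMP, scan, lmp_date=dt.date(2023, 1, 1))
ga = ga_days(dating)
print(f"gestational age at scan: {ga} days ({ga // 7}+{ga % 7} weeks)")

# the same conception event dated from the conception date lands on the
# same gestational age (the 14-day convention)
alt = DatingInfo(DatingMethod.CONCEPTION, scan, conception_date=dt.date(2023, 1, 15))
print(f"conception-dated:        {ga_days(alt)} days")

curves = default_curves()
measurements = {
    Marker.GSMD: 22.0,   # mm — small for 69 days
    Marker.YSMD: 6.8,    # mm — large
    Marker.CRL: 8.0,     # mm — short
    Marker.HR: 108.0,    # bpm — slow
}
for mk, value in measurements.items():
    res = to_centile(Measurement(mk, value, ga), curves[mk])
    print(f"{mk.value:4s} {value:6.1f} -> centile {res.centile:5.1f} (z = {res.z:+.2f})")

# A centile below 5 (GSMD, CRL, HR) or at/above 95 (YSMD) counts as an
# extreme marker; all four together form the tetrad of aneuploidy.
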