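"""Marker-based digestibility: ATTD from diet/fecal nutrient and AIA levels.

Acid-insoluble ash (AIA) passes through the gut undigested, so comparing
nutrient-to-marker ratios between diet and feces yields the apparent
total-tract digestibility without total fecal collection.
"""

from fibromics import DigestibilityRecord, GrowthRecord, attd, growth_summary, linear_trend

# one pig's total-dietary-fiber record: concentrations in % of dry matter
rec = DigestibilityRecord(
    pig_id="MS-CON-1", nutrient="TDF", dc_d=15.0, dc_f=20.0, aia_d=1.2, aia_f=4.0
)
print(f"ATTD of TDF: {attd(rec):.2f} %")
# 100·(1 − (20·1.2)/(15·4)) = 60%: 60% of ingested fiber disappeared in transit.

growth = GrowthRecord(
    pig_id="MS-CON-1",
    daily_intake_kg=[2.0] * 28,
    weight_kg=[60.0, 74.0],
    weight_days=[0, 28],
)
g = growth_summary(growth)
print(f"ADFI {g['ADFI']:.2f} kg/d, ADG {g['ADG']:.2f} kg/d, F/G {g['F_over_G']:.2f}")

# linear polynomial contrast of an outcome on the actual wheat-bran levels
levels = [0.0, 7.0, 10.5, 14.0] * 7  # 7 pigs per diet
outcome = [3.0 + 0.05 * lv for lv in levels]  # F/G worsens with fiber
t = linear_trend(outcome, levels)
print(f"linear trend: slope {t['slope']:.3f} per % wheat bran, p = {t['p_linear']:.2g}")
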