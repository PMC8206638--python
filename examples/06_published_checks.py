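"""Recompute the group statistics that depend only on published tables.

The membership-count distributions and per-subject intakes printed in the
study's tables are inputs the statistics can be re-run on: the paired t-test
on rich-club membership counts, the hub-table counterpart, the intake
summary, and both readings of the intake effect size.
"""

from megnet.published import (
    intake_summary,
    membership_change_test,
    reproduce_published_checks,
)

rc = membership_change_test("rich_club")
print(f"rich-club membership change: t({rc.df}) = {rc.statistic:.2f}, p = {rc.p_value:.3f}")

hub = membership_change_test("hub")
print(f"hub membership change:       t({hub.df}) = {hub.statistic:.2f}, p = {hub.p_value:.3f}")

s = intake_summary()
print(f"free-access intake: mean {s['mean_g_per_kg']:.1f} g/kg, SD {s['sd_g_per_kg']:.1f}")
print(f"  one-sample d vs 1.5 g/kg induction dose: {s['cohens_d_vs_induction_dose']:.2f}")
print()
print(reproduce_published_checks())
print()
print("Rich-club membership became significantly less consistent between")
print("timepoints (p ~ 0.022); the hub distribution did not change reliably.")
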