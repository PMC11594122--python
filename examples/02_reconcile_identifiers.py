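"""Reconcile two tract layers with different subdivision schemes.

Census boundary files and outcome tables often subdivide tracts
differently: the same base tract may appear as "1201.05"/"1201.06" in
one layer and as GEOIDs ...120105/...120106 in the other. Zeroing the
two subdivision digits, dissolving the repeats, and merging rates by
population weight produces comparable layers that can then be matched.
"""

import tractscape as ts
from tractscape.reconcile import tract_code
from tractscape.synthetic import reconciliation_fixture

# one base tract split into two subdivisions: merge is population-weighted
rate = ts.merge_outcomes([(1000, 30.0), (3000, 40.0)])
print(f"merged rate of a 1000/3000-person pair at 30%/40%: {rate:.1f}%")

layer_a, layer_b = reconciliation_fixture(seed=0)
joined_a = ts.dissolve_by_base(layer_a)   # boundary-style layer, decimal names
joined_b = ts.dissolve_by_base(layer_b)   # outcome-style layer, 11-digit GEOIDs
print(f"boundary layer: {len(layer_a)} records -> {len(joined_a)} joined tracts")
print(f"outcome layer:  {len(layer_b)} records -> {len(joined_b)} joined tracts")

report = ts.match_joined_sets(
    {tract_code(j.base_id) for j in joined_a},
    {tract_code(j.base_id) for j in joined_b},
)
print(f"matched: {len(report.matched)}; unmatched: {len(report.unmatched_a)} on the "
      f"boundary side, {len(report.unmatched_b)} on the outcome side")
# The matched set is the usable analysis universe: tracts with both a
# polygon and an outcome rate.
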