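"""Classify redesigned pores into the three closure topologies.

Builds one archetype of each pore-closure family and shows the geometric
metrics the classifier uses: OCD (off-center closure) displaces the open
centre; UCD (uniform closure) shrinks it concentrically with bulky groups
in one plane; CSD (cork-screw) twists the open centre along the axis via
alternating long/short side chains.
"""

import poredesign as pdsg
from poredesign.design_classifier import classify_design, compute_metrics
from poredesign.synthetic_fixtures import make_archetype_design, make_cylinder_cavity

wt_profile = pdsg.compute_profile(make_cylinder_cavity(10.3, height=30.0))

print(f"{'kind':>4}  {'offset Å':>8}  {'z-spread Å':>10}  {'twist °':>8}  {'altern.':>7}  label")
for kind in ("OCD", "UCD", "CSD"):
    cand = make_archetype_design(kind)
    m = compute_metrics(cand, wt_profile)
    label = classify_design(m)
    print(
        f"{kind:>4}  {m.center_offset:8.2f}  {m.bulky_z_spread:10.2f}  "
        f"{m.twist_span:8.1f}  {m.alternation_score:7.2f}  {label}"
    )
# Decision rule: offset > 1.5 Å -> OCD; else twist > 45° with alternation
# > 0.5 -> CSD; else UCD.  Each archetype lands in its intended class.
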