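"""Screen a proteome for aquaporins and assign standardized names.

Builds a small synthetic cohort (tandem arrays + singletons + unrelated
background proteins), screens it against a 35-member reference set by exact
pairwise alignment, applies the 40/60% identity ladder and tags paralogs
a, b, c, ... by chromosome order.
"""

from mipfam import synthetic_data as sd
from mipfam.family_classify import assign_nomenclature, screen_candidates

truth = sd.make_annotation(seed=23)
refs = sd.make_refset(include_xip=True)

assignments = screen_candidates(list(truth.proteins.values()), refs)
named = assign_nomenclature(assignments, truth.models)

print(f"{'gene':<9} {'name':<9} {'best ref':<10} {'ident%':>7} call/subfamily")
for a in named:
    print(f"{a.query_id:<9} {a.standardized_name:<9} {a.best_ref_id:<10} "
          f"{a.best_identity_pct:>7.1f} {a.family_call}/{a.subfamily}")

# Each row is one retained protein: identity > 60% inherits the reference's
# subfamily, 40-60% is family-level only, and shared ortholog groups get
# paralog suffixes (e.g. PIP1;3a/PIP1;3b from one tandem array).
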