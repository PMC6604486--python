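"""Profile aquaporin structural motifs.

Generates one diverged protein per subfamily and reads its NPA boxes, ar/R
selectivity filter (H2/H5/LE1/LE2), Froger positions and TM helices through
template-anchored alignment, then assigns the ar/R group.
"""

from mipfam import synthetic_data as sd
from mipfam.motif_profile import default_templates, map_positions_best

templates = default_templates()

print(f"{'gene':<16} {'NPA1':<5} {'NPA2':<5} {'ar/R':<8} {'group':<8} TMs")
for i, subfamily in enumerate(sorted(templates)):
    rec, _ = sd.make_protein(subfamily, 20.0, seed=100 + i,
                             record_id=f"{subfamily}_demo")
    p = map_positions_best(rec, templates)
    tetrad = "".join(p.arR_tetrad())
    print(f"{p.query_id:<16} {p.npa1.triplet:<5} {p.npa2.triplet:<5} "
          f"{tetrad:<8} {p.group:<8} {len(p.tm_segments)}")

# The ar/R tetrad determines the group: F/H/T/R marks PIPs, H/I/A/V the
# TIP-I group, W/V/A/R NIP-I, and so on; six TM segments is the canonical
# aquaporin architecture.
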