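"""Detecting what a de novo assembler broke: split transcripts, frameshifts.

Two hallmarks of assembly artifacts are (1) one protein split across two
transcripts that share an exact junction peptide, and (2) a single
transcript whose domains only make sense when read across two different
frames (an indel moved the downstream half out of frame).
"""

from domainfirst import Plant, PlantSpec, RunConfig, generate, run_novel
from domainfirst.synthfix import default_profiles, plant_reference_panel

gt = generate(PlantSpec(
    n_background=8,
    seed=21,
    plants=(
        Plant("PLCG-like", frame=1, error="split",
              split_after_domain=2, overlap=12),
        Plant("BLNK-like", frame=-1, error="frameshift",
              split_after_domain=2),
    ),
))
res = run_novel(gt.transcripts, plant_reference_panel(), RunConfig(seed=2),
                profiles=default_profiles())

for call in res.calls:
    if call.merge_partner is not None:
        print(f"{call.accession}: category {call.category}, merges with "
              f"{call.merge_partner} over the {len(call.overlap_peptide)}-aa "
              f"junction {call.overlap_peptide!r}")
    if call.frame_split is not None:
        parts = ", ".join(
            f"frame {f:+d} carries {'+'.join(doms)}"
            for f, doms in sorted(call.frame_split.assignments.items())
        )
        print(f"{call.accession}: category {call.category}, frame-split "
              f"({parts})")

rep = min(a for c in res.calls if c.merge_partner
          for a in (c.accession, c.merge_partner))
merged = res.merged_proteins[rep]
print(f"reconstructed full-length protein: {len(merged)} aa "
      f"(neither fragment alone encodes it)")
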