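"""Six-frame translation, coordinate mapping, and the ORF length convention.

A transcript has no annotated reading frame, so we translate all six frames
and keep track of how protein coordinates map back to the nucleotide
sequence.  The ORF convention excludes the stop codon: a 951-nt coding
stretch encodes a 317-residue protein.
"""

import random

from domainfirst import OrfPolicy, Transcript, find_all_orfs, longest_orf
from domainfirst.sixframe import six_frame_translate

CODON = {
    "M": "ATG", "K": "AAA", "L": "CTT", "D": "GAT", "S": "TCT",
    "G": "GGT", "W": "TGG", "H": "CAT", "R": "CGT", "E": "GAA",
}

# Build a transcript with a known 317-residue coding region.
rng = random.Random(4)
protein = "M" + "".join(rng.choice("KLDSGWHRE") for _ in range(316))
cds = "".join(CODON[a] for a in protein)
transcript = Transcript("demo.1", "GGC" + cds + "TAA" + "GGC")
print(f"transcript length: {len(transcript.sequence)} nt "
      f"(coding stretch {len(cds)} nt, stop excluded)")

translations = six_frame_translate(transcript)
print(f"{len(translations)} frame translations: "
      + ", ".join(str(ft.id) for ft in translations))

best = longest_orf(find_all_orfs(translations, OrfPolicy()))
print(f"longest ORF: {len(best.protein)} aa on frame {best.id.frame:+d} "
      f"-> a {best.nt_end - best.nt_start + 1}-nt coding stretch")

# Protein coordinates round-trip to nucleotide coordinates.
cmap = next(ft for ft in translations if ft.id == best.id).coordinate_map
nt = cmap.protein_to_nucleotide(best.protein_start, best.protein_end)
print(f"ORF protein positions {best.protein_start}..{best.protein_end} "
      f"map to transcript nt {nt[0]}..{nt[1]}")
assert nt == (best.nt_start, best.nt_end)
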