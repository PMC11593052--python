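"""Pre-annotation hygiene: removing and trimming contaminated transcripts.

Assembled transcriptomes are screened before annotation: whole sequences
flagged as contaminant are removed, and sequences with a contaminated end
are trimmed to the clean interval.  Removal takes precedence over trimming,
and the arithmetic is strict: input = removed + output.
"""

import random

from domainfirst import Transcript, contamination_filter

rng = random.Random(6)
transcripts = [
    Transcript(f"T{i:05d}.1", "".join(rng.choice("ACGT") for _ in range(120)))
    for i in range(1000)
]

remove = [t.accession for t in transcripts[:37]]
trim = {t.accession: (1, 60) for t in transcripts[37:42]}

cleaned, counts = contamination_filter(transcripts, remove, trim)
print(f"input {counts['n_input']}, removed {counts['n_removed']}, "
      f"trimmed {counts['n_trimmed']}, output {counts['n_output']}")
assert counts["n_input"] - counts["n_removed"] == counts["n_output"]

trimmed = next(t for t in cleaned if t.accession == transcripts[37].accession)
print(f"{trimmed.accession} trimmed from 120 nt to {len(trimmed.sequence)} nt")
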