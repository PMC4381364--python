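"""Scan a transcript for miRNA target sites under the five plant rules.

Scoring per position (from the miRNA 5' end): Watson-Crick 0, G:U wobble
0.5, mismatch 1.  A site passes when total <= 4, no more than two adjacent
mismatches, seed region (1-9) <= 1, center (10-11) perfect, and 5' half
(1-12) <= 2.5.
"""

import numpy as np

import saltmir as sm
from saltmir._util import revcomp

MIRNA = "UGGAGCUCCCUUCAUUCCAAU"

rng = np.random.default_rng(4)
backbone = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
site = revcomp(MIRNA.replace("U", "T"))  # perfect-complement site
transcript = backbone[:250] + site + backbone[250:]

hits = sm.scan(MIRNA, {"SPL-like": transcript})
for h in hits:
    print(f"{h.mirna} -> {h.transcript}:{h.site_start}-{h.site_end} "
          f"(total={h.mm_total}, seed={h.mm_1to9}, center={h.mm_10to11})")
    print(h.alignment)
# The planted perfect-complement site is reported with all counters at zero;
# random windows essentially never satisfy all five rules at once.
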