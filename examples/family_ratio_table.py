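"""Known-miRNA family abundance and Na200/CK expression ratios.

Uses published per-family read counts as inputs to the family-table
arithmetic: the ratio column is the raw Na200/CK read ratio rounded half-up
to two decimals, with '_' printed when the family has no control reads.
"""

import saltmir as sm


def fam(ref, family, ck, na):
    return sm.MirnaMatch(sm.SequenceTag("A" * 21, ck, na), ref, family, 0)


matches = [
    fam("miR395a", "miR395", 95, 48_134),
    fam("miR164a", "miR164", 21_869, 70_350),
    fam("miR158a", "miR158", 699_743, 3_592_759),
    fam("miR161", "miR161", 0, 101),
]
table = sm.family_table(matches)
print(table.to_string(index=False))
# A ratio of 506.67 means miR395 reads rose ~500-fold under salt stress;
# '_' marks a family absent from the control library (ratio undefined).
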