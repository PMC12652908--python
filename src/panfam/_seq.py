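"""Small shared sequence helpers (standard nuclear genetic code)."""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # standard code

CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_COMP = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                      "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS; '*' for stops, 'X' for ambiguous codons."""
    aa = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3].upper()
        if codon in CODON_TO_AA:
            aa.append(CODON_TO_AA[codon])
        elif codon in STOP_CODONS:
            aa.append("*")
        else:
            aa.append("X")
    return "".join(aa)


def trim_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds
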