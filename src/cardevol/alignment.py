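"""Aligned sequence containers.

``ProteinAlignment`` holds residue matrices over the 20 amino acids plus gap;
``CodonAlignment`` holds in-frame sense-codon matrices over the 61-codon
alphabet.  Both encode sequences to integer state codes (-1 marks missing
data: gaps, ``X`` and ambiguous codons), which downstream likelihood code
treats as fully ambiguous.
"""

from __future__ import annotations

import numpy as np

from .io import SequenceRecord
from .models import AA_INDEX, CODON_INDEX, STOP_CODONS

__all__ = ["ProteinAlignment", "CodonAlignment"]


class _Alignment:
    def __init__(self, records):
        records = [
            r if isinstance(r, SequenceRecord) else SequenceRecord(*r)
            for r in records
        ]
        if not records:
            raise ValueError("alignment must contain at least one sequence")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal lengths")
        self.records = records
        self.ids = ids

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def taxon_set(self) -> frozenset:
        return frozenset(self.ids)

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.ids.index(taxon)]

    def subset(self, taxa):
        keep = [r for r in self.records if r.id in set(taxa)]
        return type(self)(keep)


class ProteinAlignment(_Alignment):
    """Aligned protein sequences; codes are indices into ``AA_ORDER``,
    -1 for gap or ``X``."""

    n_states = 20

    def __init__(self, records):
        super().__init__(records)
        self.n_sites = len(self.records[0].seq)
        codes = np.full((len(self.records), self.n_sites), -1, dtype=np.int16)
        for i, rec in enumerate(self.records):
            for j, ch in enumerate(rec.seq.upper()):
                idx = AA_INDEX.get(ch)
                if idx is not None:
                    codes[i, j] = idx
                elif ch not in ("-", "X", "?"):
                    raise ValueError(
                        f"unknown residue {ch!r} at {rec.id} column {j + 1}"
                    )
        self.codes = codes

    def presence_matrix(self) -> np.ndarray:
        """Presence(1)/absence(0) coding of residues vs gaps, for indel
        parsimony."""
        return (self.codes >= 0).astype(np.int8)


class CodonAlignment(_Alignment):
    """Aligned in-frame coding sequences; codes index the 61 sense codons,
    -1 for gapped or ambiguous codons.  Internal stop codons are an error."""

    def __init__(self, records):
        super().__init__(records)
        seq_len = len(self.records[0].seq)
        if seq_len % 3 != 0:
            raise ValueError("codon alignment length must be divisible by 3")
        self.n_sites = seq_len // 3
        codes = np.full((len(self.records), self.n_sites), -1, dtype=np.int16)
        for i, rec in enumerate(self.records):
            seq = rec.seq.upper()
            for j in range(self.n_sites):
                codon = seq[3 * j:3 * j + 3]
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"stop codon {codon} at {rec.id} codon {j + 1}"
                    )
                codes[i, j] = CODON_INDEX.get(codon, -1)
        self.codes = codes

    @property
    def n_states(self):
        return len(CODON_INDEX)
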