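"""Codon alignments partitioned into peptide-binding-region (PBR) and non-PBR sites.

MHC class I/II genes carry a small set of codons whose residues contact bound
peptides (the PBR).  The analyses in this package partition every pairwise
comparison into synonymous changes, nonsynonymous changes outside the PBR and
nonsynonymous changes inside the PBR, so the alignment container keeps an
explicit, 1-based codon mask alongside the sequences.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "AlignmentError",
    "FrameError",
    "MaskError",
    "PbrMask",
    "CodonAlignment",
    "read_alignment",
    "write_alignment",
    "load_pbr_mask",
    "translate",
    "GENETIC_CODE",
    "STOP",
    "AMBIGUOUS",
]

VALID_CHARS = frozenset("ACGT-N")
STOP = "*"
AMBIGUOUS = "X"

_table = CodonTable.unambiguous_dna_by_id[1]
#: forward table of the standard genetic code, stop codons mapped to "*"
GENETIC_CODE: dict[str, str] = dict(_table.forward_table)
for _c in _table.stop_codons:
    GENETIC_CODE[_c] = STOP


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment."""


class FrameError(ValueError):
    """Alignment length is not a whole number of codons."""


class MaskError(ValueError):
    """A PBR mask is malformed or incompatible with the alignment."""


def translate(codon: str) -> str:
    """Translate a single codon under the standard genetic code.

    Returns the one-letter amino acid, ``"*"`` for a stop codon, or ``"X"``
    for any codon containing a gap, ``N`` or other non-ACGT character.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    codon = codon.upper()
    return GENETIC_CODE.get(codon, AMBIGUOUS)


@dataclass(frozen=True)
class PbrMask:
    """Ordered set of 1-based codon indices making up the PBR."""

    codon_indices: tuple[int, ...]
    provenance: str = "user"

    def __post_init__(self) -> None:
        idx = self.codon_indices
        if any(i <= 0 for i in idx):
            raise MaskError("codon indices must be positive (1-based)")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise MaskError("codon indices must be strictly increasing with no duplicates")
        object.__setattr__(self, "codon_indices", tuple(int(i) for i in idx))

    def __len__(self) -> int:
        return len(self.codon_indices)

    def __contains__(self, codon_index: int) -> bool:
        return codon_index in set(self.codon_indices)

    def as_set(self) -> frozenset[int]:
        return frozenset(self.codon_indices)


@dataclass
class CodonAlignment:
    """In-frame nucleotide alignment with an optional PBR codon mask.

    ``records`` maps allele name to its aligned nucleotide string; all strings
    have equal length, a multiple of three.  ``pbr_codons`` uses 1-based codon
    numbering on the supplied frame (mature-protein numbering for the shipped
    DRB1 mask).  Codons containing ``-`` or ``N`` are kept and flagged, never
    silently dropped; pairwise operations exclude them per pair.
    """

    records: dict[str, str]
    pbr_mask: PbrMask | None = None
    region_bounds: tuple[int, int] | None = None
    flagged_codons: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise FrameError(f"alignment length {length} is not a multiple of 3")
        bad = set()
        for name, seq in self.records.items():
            seq = seq.upper()
            extra = set(seq) - VALID_CHARS
            if extra:
                raise AlignmentError(f"record {name!r} has invalid characters {sorted(extra)}")
            self.records[name] = seq
            bad |= {c for c in (set(seq) & {"-", "N"})}
        if self.pbr_mask is not None:
            self._check_mask(self.pbr_mask)
        self.flagged_codons = {
            name: tuple(
                i + 1
                for i in range(length // 3)
                if set(seq[3 * i : 3 * i + 3]) & {"-", "N"}
            )
            for name, seq in self.records.items()
        }
        self.flagged_codons = {k: v for k, v in self.flagged_codons.items() if v}

    def _check_mask(self, mask: PbrMask) -> None:
        if mask.codon_indices and mask.codon_indices[-1] > self.n_codons:
            raise MaskError(
                f"mask index {mask.codon_indices[-1]} exceeds {self.n_codons} codons"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def names(self) -> list[str]:
        return list(self.records)

    def codons(self, name: str) -> list[str]:
        seq = self.records[name]
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]

    def aa_string(self, name: str, codon_indices: Iterable[int] | None = None) -> str:
        """Amino-acid translation of a record, optionally restricted to codons."""
        cods = self.codons(name)
        if codon_indices is None:
            return "".join(translate(c) for c in cods)
        return "".join(translate(cods[i - 1]) for i in codon_indices)

    def pbr_aa(self, name: str) -> str:
        if self.pbr_mask is None:
            raise MaskError("alignment has no PBR mask")
        return self.aa_string(name, self.pbr_mask.codon_indices)

    def with_mask(self, mask: PbrMask) -> "CodonAlignment":
        self._check_mask(mask)
        return CodonAlignment(dict(self.records), mask, self.region_bounds)

    def subset(self, names: Iterable[str]) -> "CodonAlignment":
        names = list(names)
        unknown = [n for n in names if n not in self.records]
        if unknown:
            raise AlignmentError(f"unknown alleles: {unknown}")
        if not names:
            raise AlignmentError("empty allele subset")
        return CodonAlignment(
            {n: self.records[n] for n in names}, self.pbr_mask, self.region_bounds
        )

    def nonpbr_codon_indices(self) -> list[int]:
        masked = self.pbr_mask.as_set() if self.pbr_mask else frozenset()
        return [i for i in range(1, self.n_codons + 1) if i not in masked]


def read_alignment(
    path: str | Path,
    frame_offset: int = 0,
    pbr_mask: PbrMask | None = None,
) -> CodonAlignment:
    """Read an aligned FASTA of coding sequences.

    ``frame_offset`` drops that many leading codons (e.g. a leader peptide)
    so that codon 1 is the first codon of the mature protein, matching the
    numbering of PBR masks.  Duplicate allele names are rejected.
    """
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AlignmentError(f"duplicate allele name {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"sequences are not aligned; lengths {sorted(lengths)}")
    if frame_offset:
        if frame_offset < 0:
            raise FrameError("frame_offset must be >= 0 codons")
        records = {k: v[3 * frame_offset :] for k, v in records.items()}
    return CodonAlignment(records, pbr_mask)


def write_alignment(alignment: CodonAlignment, path: str | Path) -> None:
    """Write the alignment back out as FASTA (round-trips with read_alignment)."""
    with open(path, "w") as fh:
        for name, seq in alignment.records.items():
            fh.write(f">{name}\n{seq}\n")


_BUILTIN_MASKS = {"drb1-27": "drb1_pbr27.txt"}


def load_pbr_mask(source: str | Path | Iterable[int], alignment: CodonAlignment | None = None) -> PbrMask:
    """Load a PBR mask from a builtin name, a one-column text file, or indices.

    The builtin ``"drb1-27"`` is the 27-codon HLA-DRB1 mask (mature-protein
    numbering) reconstructed from the published crystal-structure contact
    residues plus sites 57, 67 and 90.  When ``alignment`` is given the mask
    is validated against its codon count.
    """
    provenance: str
    if isinstance(source, (str, Path)) and str(source) in _BUILTIN_MASKS:
        name = _BUILTIN_MASKS[str(source)]
        text = (
            importlib.resources.files("pbrhet").joinpath("data", name).read_text()
        )
        indices = _parse_mask_text(text)
        provenance = f"builtin:{source}"
    elif isinstance(source, (str, Path)):
        p = Path(source)
        if not p.exists():
            raise MaskError(f"mask file {p} not found and not a builtin name")
        indices = _parse_mask_text(p.read_text())
        provenance = str(p)
    else:
        indices = [int(i) for i in source]
        provenance = "explicit"
    if sorted(set(indices)) != sorted(indices):
        raise MaskError("duplicate codon indices in mask")
    mask = PbrMask(tuple(sorted(indices)), provenance)
    if alignment is not None:
        alignment._check_mask(mask)
    return mask


def _parse_mask_text(text: str) -> list[int]:
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(int(line))
    if not out:
        raise MaskError("mask file lists no codon indices")
    return out
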