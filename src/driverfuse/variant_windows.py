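"""Reference-context extraction around somatic single-nucleotide variants.

A variant is represented by the 2xL "mutation pair" matrix: the reference
nucleotide context in row 0 and the same context with the alternate base
substituted at the centre in row 1, so the two rows differ in exactly one
column.  L = 2w + 1 for window radius w; positions falling outside the
chromosome are padded with the missing-place symbol ``n``.

Coordinates are 1-based on input (VCF convention) and 0-based half-open
internally.  All sequence handling is lowercase over the alphabet
``{a, c, g, t, n}``; variant ref/alt bases are stored uppercase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: internal sequence alphabet; anything else in a reference is mapped to "n"
ALPHABET = "acgtn"
VALID_BASES = frozenset("ACGT")
LABELS = ("driver", "passenger", "unlabeled")

_TRANS = str.maketrans(
    {c: (c if c in "acgt" else "n") for c in map(chr, range(128))}
)


class ReferenceMismatchError(ValueError):
    """Raised when the stored reference base disagrees with a variant's REF."""


@dataclass(frozen=True)
class Variant:
    """One biallelic genomic substitution.

    pos is the 1-based coordinate of the substituted base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        object.__setattr__(self, "label", _normalize_label(self.label))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def _normalize_label(label: str | None) -> str:
    if label is None or label == "" or label == ".":
        return "unlabeled"
    norm = str(label).strip().lower()
    if norm not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    return norm


class ReferenceSequenceStore:
    """In-memory per-chromosome sequences, lowercase over {a,c,g,t,n}."""

    def __init__(self, sequences: dict[str, str] | None = None):
        self._seqs: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self._seqs:
            raise ValueError(f"duplicate chromosome identifier {name!r}")
        self._seqs[name] = seq.lower().translate(_TRANS)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def sequence(self, name: str) -> str:
        return self._seqs[name]

    def fetch(self, name: str, start0: int, end0: int) -> str:
        """Substring on 0-based half-open coordinates, 'n'-padded out of bounds."""
        if name not in self._seqs:
            raise KeyError(f"chromosome {name!r} not in reference store")
        seq = self._seqs[name]
        left = max(start0, 0)
        right = min(end0, len(seq))
        core = seq[left:right] if right > left else ""
        return "n" * (left - start0) + core + "n" * (end0 - right)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_reference(path: str | Path) -> ReferenceSequenceStore:
    """Load a multi-record FASTA into a :class:`ReferenceSequenceStore`.

    Sequences are lowercased; ambiguity codes and any symbol outside
    {a,c,g,t} become 'n'.  Duplicate record identifiers are an error.
    """
    store = ReferenceSequenceStore()
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        store.add(record.id, str(record.seq))
        n += 1
    if n == 0:
        raise ValueError(f"no FASTA records found in {path}")
    logger.info("loaded %d reference sequences from %s", n, path)
    return store


@dataclass
class VariantReadResult:
    """Parsed variants plus bookkeeping on rows that were not ingested."""

    variants: list[Variant]
    n_skipped_non_snv: int = 0
    n_rejected: int = 0

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def read_variants(
    path: str | Path, format: Literal["tsv", "vcf"] = "tsv"
) -> VariantReadResult:
    """Read biallelic SNVs from a 5-column TSV (CHR POS REF ALT [LABEL]) or VCF.

    Non-SNV rows (indels, MNVs, multi-allelic ALTs) are skipped and counted;
    rows with REF == ALT are rejected and counted.  Malformed TSV rows raise
    with the offending line number.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown variant format {format!r}")


def _read_tsv(path: str | Path) -> VariantReadResult:
    result = VariantReadResult([])
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated fixtures
                fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns, got {len(fields)}")
            if lineno == 1 and fields[0].strip().upper() in {"CHR", "CHROM", "#CHROM"}:
                continue
            chrom, pos_s, ref, alt = fields[:4]
            label = fields[4] if len(fields) > 4 else "unlabeled"
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer position {pos_s!r}") from exc
            if len(ref) != 1 or len(alt) != 1 or ref.upper() not in VALID_BASES or alt.upper() not in VALID_BASES:
                result.n_skipped_non_snv += 1
                continue
            if ref.upper() == alt.upper():
                result.n_rejected += 1
                continue
            try:
                result.variants.append(Variant(chrom, pos, ref, alt, label))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    logger.info(
        "read %d variants from %s (%d non-SNV skipped, %d rejected)",
        len(result.variants), path, result.n_skipped_non_snv, result.n_rejected,
    )
    return result


def _read_vcf(path: str | Path) -> VariantReadResult:
    import pysam

    result = VariantReadResult([])
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in VALID_BASES
                or alts[0].upper() not in VALID_BASES
            ):
                result.n_skipped_non_snv += 1
                continue
            if rec.ref.upper() == alts[0].upper():
                result.n_rejected += 1
                continue
            label = rec.info.get("LABEL", "unlabeled")
            if isinstance(label, tuple):
                label = label[0]
            result.variants.append(Variant(rec.chrom, rec.pos, rec.ref, alts[0], str(label)))
    logger.info(
        "read %d variants from %s (%d non-SNV skipped, %d rejected)",
        len(result.variants), path, result.n_skipped_non_snv, result.n_rejected,
    )
    return result


@dataclass(frozen=True)
class MutationPair:
    """2xL symbol matrix: reference context row plus mutated row.

    The rows differ only at the centre column (index w, 0-based); the centre
    of ``ref_row`` is the variant's reference base and the centre of
    ``alt_row`` its alternate base, both lowercase.
    """

    w: int
    ref_row: str
    alt_row: str
    variant: Variant = field(compare=False)

    def __post_init__(self) -> None:
        L = 2 * self.w + 1
        if self.w < 1:
            raise ValueError(f"window radius must be >= 1, got {self.w}")
        if len(self.ref_row) != L or len(self.alt_row) != L:
            raise ValueError(f"rows must have length {L}, got {len(self.ref_row)}/{len(self.alt_row)}")
        diffs = [i for i, (a, b) in enumerate(zip(self.ref_row, self.alt_row)) if a != b]
        if diffs != [self.w]:
            raise ValueError(f"rows must differ exactly at the centre column {self.w}, differ at {diffs}")

    @property
    def length(self) -> int:
        return 2 * self.w + 1

    @property
    def matrix(self) -> tuple[str, str]:
        return (self.ref_row, self.alt_row)

    def recover_variant(self) -> tuple[int, str, str]:
        """(pos, ref, alt) recovered from the matrix plus the anchoring coordinate."""
        return (self.variant.pos, self.ref_row[self.w].upper(), self.alt_row[self.w].upper())


def extract_pair(
    store: ReferenceSequenceStore,
    v: Variant,
    w: int,
    on_ref_mismatch: Literal["reject", "warn"] = "reject",
) -> MutationPair:
    """Extract the 2x(2w+1) mutation-pair matrix around ``v``.

    Window positions outside [1, chromosome length] are filled with 'n'.
    If the stored base at ``v.pos`` differs from ``v.ref`` the behaviour
    follows ``on_ref_mismatch``: ``reject`` raises, ``warn`` logs and keeps
    the store's base in row 0 (row 1 still carries the alternate base).
    """
    if w < 1:
        raise ValueError(f"window radius must be >= 1, got {w}")
    if v.chrom not in store:
        raise KeyError(f"chromosome {v.chrom!r} not in reference store")
    center0 = v.pos - 1
    ref_row = store.fetch(v.chrom, center0 - w, center0 + w + 1)
    store_base = ref_row[w]
    if store_base != v.ref.lower():
        if on_ref_mismatch == "reject":
            raise ReferenceMismatchError(
                f"reference mismatch at {v.key}: store has {store_base!r}, variant REF is {v.ref!r}"
            )
        logger.warning(
            "reference mismatch at %s: store has %r, using store base in row 0", v.key, store_base
        )
    alt_row = ref_row[:w] + v.alt.lower() + ref_row[w + 1 :]
    return MutationPair(w=w, ref_row=ref_row, alt_row=alt_row, variant=v)


def extract_pairs(
    store: ReferenceSequenceStore,
    variants: Iterable[Variant],
    w: int,
    on_ref_mismatch: Literal["reject", "warn"] = "reject",
) -> list[MutationPair]:
    return [extract_pair(store, v, w, on_ref_mismatch) for v in variants]


def write_pairs(pairs: Iterable[MutationPair], path: str | Path) -> None:
    """Tab-separated dump: chrom, pos, ref, alt, label, row0, row1."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlabel\trow0\trow1\n")
        for p in pairs:
            v = p.variant
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.label}\t{p.ref_row}\t{p.alt_row}\n")


def read_pairs(path: str | Path) -> list[MutationPair]:
    """Inverse of :func:`write_pairs`."""
    pairs: list[MutationPair] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError(f"{path}: missing pair-table header")
        for line in fh:
            chrom, pos, ref, alt, label, row0, row1 = line.rstrip("\n").split("\t")
            v = Variant(chrom, int(pos), ref, alt, label)
            pairs.append(MutationPair(w=(len(row0) - 1) // 2, ref_row=row0, alt_row=row1, variant=v))
    return pairs
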