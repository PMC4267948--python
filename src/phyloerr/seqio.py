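"""Alignment container, FASTA/PHYLIP I/O, site-pattern compression, SNP density.

Sequences live over the IUPAC nucleotide alphabet plus ``-`` and ``?`` (both
read as missing data, equivalent to N in likelihood computations, per the
PHYLIP convention).  Input is uppercased and U is mapped to T on read, so an
``Alignment`` always holds DNA symbols.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTRYSWKMBDHVN-?")

_TRANSLATE = str.maketrans({"U": "T", "u": "T"})


class AlignmentError(ValueError):
    """Malformed alignment file or invalid alignment content."""


def _normalize(seq: str) -> str:
    return seq.translate(_TRANSLATE).upper()


@dataclass
class Alignment:
    """Equal-length named nucleotide sequences.

    Sequences are normalized on construction (uppercase, U->T) and every
    symbol is validated against the IUPAC alphabet; violations raise
    :class:`AlignmentError` naming the offending taxon and 1-based column.
    """

    taxon_names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxon_names) != len(self.sequences):
            raise AlignmentError("taxon_names and sequences differ in length")
        if not self.taxon_names:
            raise AlignmentError("alignment has no taxa")
        seen = set()
        for name in self.taxon_names:
            if not name:
                raise AlignmentError("empty taxon name")
            if name in seen:
                raise AlignmentError(f"duplicate taxon name {name!r}")
            seen.add(name)
        self.sequences = [_normalize(s) for s in self.sequences]
        n = len(self.sequences[0])
        if n < 1:
            raise AlignmentError("alignment has zero sites")
        for name, seq in zip(self.taxon_names, self.sequences):
            if len(seq) != n:
                raise AlignmentError(
                    f"ragged alignment: taxon {name!r} has {len(seq)} sites, expected {n}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                col = next(i for i, c in enumerate(seq) if c in bad)
                raise AlignmentError(
                    f"illegal symbol {seq[col]!r} in taxon {name!r}, column {col + 1}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def byte_matrix(self) -> np.ndarray:
        """(n_taxa, n_sites) uint8 matrix of ASCII symbol codes."""
        return np.array(
            [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in self.sequences]
        )

    def subset(self, names: list[str]) -> "Alignment":
        """Restriction to the given taxa, preserving the given order."""
        index = {n: i for i, n in enumerate(self.taxon_names)}
        return Alignment(list(names), [self.sequences[index[n]] for n in names])


@dataclass
class SitePatterns:
    """Distinct alignment columns and their multiplicities.

    ``patterns[j]`` is the j-th distinct column as a string with one symbol
    per taxon, in order of first occurrence; ``weights[j]`` is its count.
    """

    taxon_names: list[str]
    patterns: list[str]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.int64)
        if len(self.patterns) != len(self.weights):
            raise ValueError("patterns and weights differ in length")
        if (self.weights <= 0).any():
            raise ValueError("pattern weights must be positive")

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())


def compress_patterns(aln: Alignment) -> SitePatterns:
    """Collapse identical columns; deterministic first-occurrence order."""
    mat = aln.byte_matrix()
    cols = np.ascontiguousarray(mat.T)
    counts: dict[bytes, int] = {}
    for col in cols:
        key = col.tobytes()
        counts[key] = counts.get(key, 0) + 1
    patterns = [k.decode("ascii") for k in counts]
    weights = np.fromiter(counts.values(), dtype=np.int64, count=len(counts))
    return SitePatterns(list(aln.taxon_names), patterns, weights)


def snp_density(aln: Alignment) -> float:
    """Segregating sites per kilobase.

    A column is segregating iff at least two distinct resolved bases
    (A, C, G, T) occur in it; ambiguity codes, gaps and missing data never
    count toward polymorphism.
    """
    mat = aln.byte_matrix()
    present = np.zeros(mat.shape[1], dtype=np.int8)
    for base in b"ACGT":
        present += (mat == base).any(axis=0)
    return 1000.0 * float((present >= 2).sum()) / aln.n_sites


# ---------------------------------------------------------------------------
# file I/O


def read_alignment(path: str | Path, format: str) -> Alignment:
    """Read a FASTA or PHYLIP alignment file.

    PHYLIP files may be sequential or interleaved, with whitespace-delimited
    (relaxed) taxon names.  Raises :class:`AlignmentError` on malformed input.
    """
    path = Path(path)
    if format == "fasta":
        return _read_fasta(path)
    if format == "phylip":
        return _read_phylip(path)
    raise ValueError(f"unknown alignment format {format!r} (expected 'phylip' or 'fasta')")


def write_alignment(aln: Alignment, path: str | Path, format: str) -> None:
    """Write FASTA or sequential relaxed PHYLIP."""
    path = Path(path)
    if format == "fasta":
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in zip(aln.taxon_names, aln.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")
    elif format == "phylip":
        for name in aln.taxon_names:
            if any(c.isspace() for c in name):
                raise AlignmentError(f"taxon name {name!r} contains whitespace; cannot write PHYLIP")
        with open(path, "w") as fh:
            fh.write(f"{aln.n_taxa} {aln.n_sites}\n")
            for name, seq in zip(aln.taxon_names, aln.sequences):
                fh.write(f"{name}  {seq}\n")
    else:
        raise ValueError(f"unknown alignment format {format!r} (expected 'phylip' or 'fasta')")


def _read_fasta(path: Path) -> Alignment:
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, OSError) as exc:
        raise AlignmentError(f"cannot parse FASTA file {path}: {exc}") from exc
    if not records:
        raise AlignmentError(f"no sequences found in FASTA file {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def _read_phylip(path: Path) -> Alignment:
    import dendropy

    try:
        text = path.read_text()
    except OSError as exc:
        raise AlignmentError(f"cannot read {path}: {exc}") from exc
    header = text.split("\n", 1)[0].split()
    if len(header) < 2 or not header[0].isdigit() or not header[1].isdigit():
        raise AlignmentError(
            f"{path}, line 1: expected PHYLIP header '<n_taxa> <n_sites>', got {header!r}"
        )
    n_taxa, n_sites = int(header[0]), int(header[1])
    errors = []
    for interleaved in (False, True):
        try:
            dcm = dendropy.DnaCharacterMatrix.get(
                file=io.StringIO(text),
                schema="phylip",
                strict=False,
                interleaved=interleaved,
            )
            names = [t.label for t in dcm.taxon_namespace]
            seqs = [str(dcm[t]) for t in dcm.taxon_namespace]
            aln = Alignment(names, seqs)
            if aln.n_taxa != n_taxa or aln.n_sites != n_sites:
                raise AlignmentError(
                    f"{path}: header declares {n_taxa} taxa x {n_sites} sites "
                    f"but parsed {aln.n_taxa} x {aln.n_sites}"
                )
            return aln
        except Exception as exc:  # dendropy raises its own DataError hierarchy
            errors.append(f"{'interleaved' if interleaved else 'sequential'}: {exc}")
    raise AlignmentError(f"cannot parse PHYLIP file {path} ({'; '.join(errors)})")
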