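"""Alignment container, FASTA/PHYLIP I/O, Dayhoff recoding and alignment statistics.

The two statistics implemented here — the compositional-heterogeneity X² and
the per-site biochemical diversity — are the *observed* halves of the posterior
predictive adequacy tests in :mod:`phylopp.adequacy`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

AMINO20 = "ACDEFGHIKLMNPQRSTVWY"
DAYHOFF6 = "ABCDEF"
#: symbols treated as missing data (gap plus ambiguity codes); letters that
#: belong to an alphabet (e.g. recoded class 'B') are never missing there
MISSING = set("-XBZJ*?.")

ALPHABETS = {"amino20": AMINO20, "dayhoff6": DAYHOFF6}


def missing_symbols(alphabet: str) -> set[str]:
    return MISSING - set(ALPHABETS[alphabet])


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, bad symbols, duplicate taxa)."""


@dataclass
class Alignment:
    """A taxa × columns character matrix over a declared residue alphabet.

    Parameters
    ----------
    taxa:
        Ordered, unique sequence labels.
    matrix:
        2-D array of single-character strings, one row per taxon. Symbols are
        upper-cased; gaps ``-`` and ambiguity codes (X, B, Z, J, \\*) are kept
        but treated as missing by every statistic.
    alphabet:
        ``"amino20"`` (the 20 standard residues) or ``"dayhoff6"`` (the six
        recoded classes, written A–F).
    """

    taxa: list[str]
    matrix: np.ndarray
    alphabet: str = "amino20"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-D (taxa x columns)")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.taxa)} taxon labels but {self.matrix.shape[0]} rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dupes}")
        if self.n_taxa < 2 or self.n_sites < 1:
            raise AlignmentError("need at least 2 taxa and 1 column")
        if self.alphabet not in ALPHABETS:
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        letters = set(ALPHABETS[self.alphabet]) | missing_symbols(self.alphabet)
        bad = set(self.matrix.ravel()) - letters
        if bad:
            sym = sorted(bad)[0]
            i, j = np.argwhere(self.matrix == sym)[0]
            raise AlignmentError(
                f"symbol {sym!r} at taxon {self.taxa[i]!r} column {j} is not in "
                f"alphabet {self.alphabet!r}"
            )

    # -- basic geometry ------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def states(self) -> str:
        return ALPHABETS[self.alphabet]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing cells (gaps and ambiguity codes)."""
        mask = np.zeros(self.matrix.shape, dtype=bool)
        for sym in missing_symbols(self.alphabet):
            mask |= self.matrix == sym
        return mask

    def encode(self) -> np.ndarray:
        """Integer-coded matrix: state index in the alphabet, −1 for missing."""
        idx = {c: i for i, c in enumerate(self.states)}
        out = np.full(self.matrix.shape, -1, dtype=np.int64)
        for sym, i in idx.items():
            out[self.matrix == sym] = i
        return out

    @classmethod
    def from_sequences(
        cls, taxa: Sequence[str], seqs: Sequence[str], alphabet: str = "amino20"
    ) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            offender = taxa[[len(s) for s in seqs].index(max(lengths))]
            raise AlignmentError(
                f"ragged alignment: taxon {offender!r} has a different length"
            )
        matrix = np.array([list(s.upper()) for s in seqs], dtype="<U1")
        return cls(list(taxa), matrix, alphabet)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, format: str = "fasta", alphabet: str = "amino20") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    PHYLIP files may be sequential or interleaved (autodetected); taxon names
    extend up to the first whitespace rather than a fixed 10-column field.
    """
    path = Path(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"{path}: no FASTA records found")
        return Alignment.from_sequences(
            [r.id for r in records], [str(r.seq) for r in records], alphabet
        )
    if format == "phylip":
        taxa, seqs = _read_relaxed_phylip(path)
        return Alignment.from_sequences(taxa, seqs, alphabet)
    raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'phylip')")


def _read_relaxed_phylip(path: Path) -> tuple[list[str], list[str]]:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise AlignmentError(f"{path}: empty file")
    try:
        ntax, nchar = (int(x) for x in lines[0].split()[:2])
    except (ValueError, IndexError):
        raise AlignmentError(f"{path}: bad PHYLIP header {lines[0]!r}") from None
    body = lines[1:]
    if len(body) < ntax:
        raise AlignmentError(f"{path}: header promises {ntax} taxa, found {len(body)} lines")
    taxa: list[str] = []
    seqs: list[str] = []
    for ln in body[:ntax]:
        parts = ln.split(None, 1)
        if len(parts) < 2:
            raise AlignmentError(f"{path}: cannot split taxon/sequence in line {ln!r}")
        taxa.append(parts[0])
        seqs.append(parts[1].replace(" ", ""))
    # interleaved continuation blocks: bare sequence lines cycling over taxa
    extra = body[ntax:]
    for k, ln in enumerate(extra):
        seqs[k % ntax] += ln.replace(" ", "")
    for t, s in zip(taxa, seqs):
        if len(s) != nchar:
            raise AlignmentError(
                f"{path}: taxon {t!r} has {len(s)} characters, header says {nchar}"
            )
    return taxa, seqs


def write_fasta(aln: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.matrix):
            fh.write(f">{taxon}\n")
            seq = "".join(row)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_phylip(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{aln.n_taxa} {aln.n_sites}\n")
        for taxon, row in zip(aln.taxa, aln.matrix):
            fh.write(f"{taxon}  {''.join(row)}\n")


# ---------------------------------------------------------------------------
# Dayhoff recoding
# ---------------------------------------------------------------------------

@dataclass
class RecodingScheme:
    """A partition of the 20 amino acids into disjoint classes."""

    name: str
    groups: dict[str, str]  # class letter -> member residues

    def __post_init__(self) -> None:
        members = "".join(self.groups.values())
        if len(set(members)) != len(members):
            raise ValueError(f"{self.name}: classes are not disjoint")
        if set(members) != set(AMINO20):
            raise ValueError(f"{self.name}: classes do not cover the 20 amino acids")

    @property
    def n_classes(self) -> int:
        return len(self.groups)

    def residue_to_class(self) -> dict[str, str]:
        return {res: cls for cls, residues in self.groups.items() for res in residues}

    @classmethod
    def dayhoff6(cls) -> "RecodingScheme":
        """The shipped six-class Dayhoff table."""
        text = resources.files("phylopp.data").joinpath("dayhoff6.tsv").read_text()
        groups = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            letter, residues = line.split("\t")
            groups[letter] = residues.strip()
        return cls("dayhoff6", groups)


def dayhoff_recode(aln: Alignment, scheme: RecodingScheme | None = None) -> Alignment:
    """Collapse a 20-state alignment onto the six Dayhoff classes.

    Missing symbols are preserved in place; dimensions are unchanged. Already
    recoded alignments are rejected.
    """
    if aln.alphabet != "amino20":
        raise AlignmentError("dayhoff_recode requires an amino20 alignment")
    scheme = scheme or RecodingScheme.dayhoff6()
    if scheme.n_classes != 6:
        raise ValueError("recoding to other than 6 classes is not supported here")
    table = scheme.residue_to_class()
    out = aln.matrix.copy()
    for res, cls in table.items():
        out[aln.matrix == res] = cls
    return Alignment(list(aln.taxa), out, "dayhoff6")


def write_recoded(aln: Alignment, path: str | Path, scheme: RecodingScheme | None = None) -> None:
    """Write a recoded alignment as FASTA plus a sidecar class-mapping file."""
    scheme = scheme or RecodingScheme.dayhoff6()
    write_fasta(aln, path)
    sidecar = Path(path).with_suffix(".classes.tsv")
    with open(sidecar, "w") as fh:
        for letter, residues in scheme.groups.items():
            fh.write(f"{letter}\t{residues}\n")


# ---------------------------------------------------------------------------
# Observed statistics
# ---------------------------------------------------------------------------

@dataclass
class CompositionSummary:
    """Per-taxon composition counts and the Pearson X² heterogeneity statistic."""

    taxa: list[str]
    symbols: str
    counts: np.ndarray  # taxa x symbols, gap-excluded
    global_freqs: np.ndarray
    chisq: float


@dataclass
class DiversitySummary:
    """Distinct-residue counts per column and their mean."""

    per_site: np.ndarray
    mean: float
    n_excluded_columns: int = 0


def composition_counts(aln: Alignment) -> np.ndarray:
    """Taxa × symbols count table, excluding gaps and ambiguity codes."""
    enc = aln.encode()
    k = len(aln.states)
    counts = np.zeros((aln.n_taxa, k), dtype=np.int64)
    for s in range(k):
        counts[:, s] = (enc == s).sum(axis=1)
    return counts


def composition_chisq(aln: Alignment) -> CompositionSummary:
    """Pearson X² for among-taxon compositional heterogeneity.

    Expected cell counts are (row total) × (pooled global frequency); gaps and
    ambiguities are excluded from all counts. Symbols absent from the pooled
    data contribute nothing. Identical rows give X² = 0.
    """
    counts = composition_counts(aln)
    row_tot = counts.sum(axis=1)
    if (row_tot == 0).any():
        bad = aln.taxa[int(np.argmax(row_tot == 0))]
        raise AlignmentError(f"taxon {bad!r} has no non-missing data")
    col_tot = counts.sum(axis=0)
    freqs = col_tot / col_tot.sum()
    expected = np.outer(row_tot, freqs)
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chisq = float(cells.sum())
    return CompositionSummary(list(aln.taxa), aln.states, counts, freqs, chisq)


def site_diversity(aln: Alignment) -> DiversitySummary:
    """Number of distinct non-missing residues at each column, and the mean.

    Columns with no non-missing symbol are excluded with a warning; an
    alignment made entirely of such columns is an error.
    """
    enc = aln.encode()
    k = len(aln.states)
    present = np.zeros((k, aln.n_sites), dtype=bool)
    for s in range(k):
        present[s] = (enc == s).any(axis=0)
    per_site = present.sum(axis=0)
    keep = per_site > 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise AlignmentError("every column is entirely missing")
    if n_excluded:
        warnings.warn(
            f"{n_excluded} all-missing column(s) excluded from site diversity",
            stacklevel=2,
        )
    return DiversitySummary(per_site[keep], float(per_site[keep].mean()), n_excluded)
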