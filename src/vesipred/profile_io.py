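"""Sequence and PSSM profile I/O, normalization, and synthetic profile generation.

A position-specific scoring matrix (PSSM) is the L x 20 profile produced by
iterative database search (PSI-BLAST against NR, three iterations, ASCII
output via ``-out_ascii_pssm``): row *i* holds the log-odds substitution
scores of sequence position *i* against the 20 standard amino acids, in
PSI-BLAST column order ``A R N D C Q E G H I L K M F P S T W V Y``.

All downstream feature encoders consume *normalized* profiles: every raw
log-odds score is mapped through the logistic function ``1 / (1 + exp(-x))``
so that entries lie in (0, 1).  Raw log-odds can be negative or sum to zero,
which would make product/ratio features (transition probabilities) undefined;
the logistic map is strictly monotone, so per-row argmax (the consensus
sequence) is unchanged by it.

The module also provides a synthetic profile generator so that the full
pipeline can be exercised without PSI-BLAST or external data: it draws raw
integer scores resembling BLOSUM-scaled log-odds and plants two class
signals, a mean shift on a subset of columns and an elevated probability
that consecutive rows of positive-class profiles share their argmax column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: Fixed PSI-BLAST column order; every encoder indexes against this.
AA_ORDER = "ARNDCQEGHILKMFPSTWVY"
_AA_SET = frozenset(AA_ORDER)

#: Residues accepted only under the permissive FASTA policy (mapped to X).
AMBIGUOUS_RESIDUES = frozenset("XBZUOJ")


class ProfileFormatError(ValueError):
    """Raised when a FASTA or PSSM file violates the expected format."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20-letter amino-acid alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PSSMProfile:
    """An L x 20 profile matrix in fixed PSI-BLAST column order.

    ``normalized`` is False for raw log-odds scores and True after the
    logistic map; encoders check the flag rather than guessing from values.
    """

    id: str
    scores: np.ndarray
    normalized: bool = False
    residues: str | None = None
    column_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"profile {self.id!r}: expected an L x 20 matrix, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"profile {self.id!r} has no rows")
        if self.column_order != AA_ORDER:
            raise ValueError("column_order must be the PSI-BLAST order " + AA_ORDER)
        if self.normalized:
            if not ((self.scores > 0.0) & (self.scores < 1.0)).all():
                raise ValueError(
                    f"profile {self.id!r} flagged normalized but has entries "
                    "outside (0, 1)"
                )

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def __len__(self) -> int:
        return self.length


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Conditions for the synthetic labeled-profile generator.

    Parameters
    ----------
    n_positive, n_negative
        Class sizes (positives are the vesicular-transport class, label 1).
    length_range
        Inclusive [min, max] sequence length; min must be >= 10 because the
        segmented encoders need non-empty lag windows.
    class_shift
        Mean raw-score offset added to ``shifted_columns`` in positives,
        in log-odds units (raw scores have sd ~3).
    transition_bias
        Probability in [0, 1] that a row of a positive profile is forced to
        share its argmax column with the previous row, planting the local
        transition structure that TPC/consensus features detect.
    shifted_columns
        Column indices receiving the mean shift.
    """

    n_positive: int
    n_negative: int
    length_range: tuple[int, int] = (30, 80)
    class_shift: float = 2.0
    transition_bias: float = 0.5
    seed: int = 0
    shifted_columns: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("both class counts must be >= 1")
        lo, hi = self.length_range
        if lo < 10:
            raise ValueError(
                "minimum profile length is 10: the segmented encoders need "
                f"non-empty lag windows (got {lo})"
            )
        if hi < lo:
            raise ValueError("length_range max must be >= min")
        if not 0.0 <= self.transition_bias <= 1.0:
            raise ValueError("transition_bias must lie in [0, 1]")
        if any(c < 0 or c > 19 for c in self.shifted_columns):
            raise ValueError("shifted_columns must be indices in 0..19")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, permissive: bool = False) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file, preserving record order.

    Residues are uppercased.  By default any character outside the 20-letter
    alphabet is an error naming the record and 1-based position; with
    ``permissive=True`` the ambiguity codes X/B/Z/U/O/J are mapped to X
    (excluded from composition counts downstream) and only truly illegal
    characters are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ProfileFormatError(f"{path}: no FASTA records found")
    sequences: list[ProteinSequence] = []
    for rec in records:
        residues = str(rec.seq).upper()
        cleaned = []
        for pos, ch in enumerate(residues, start=1):
            if ch in _AA_SET:
                cleaned.append(ch)
            elif permissive and ch in AMBIGUOUS_RESIDUES:
                cleaned.append("X")
            else:
                raise ProfileFormatError(
                    f"{path}: record {rec.id!r} has illegal residue {ch!r} "
                    f"at position {pos}"
                )
        sequences.append(ProteinSequence(id=rec.id, residues="".join(cleaned)))
    return sequences


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def parse_pssm(path: str | Path, id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file into a raw profile.

    The accepted dialect is the 40-column ASCII matrix: header lines, then
    one row per residue starting with the 1-based position and the residue
    letter, followed by 20 log-odds scores, 20 weighted-percentage columns
    and two trailing statistics.  Only the first 20 score columns are kept.
    """
    path = Path(path)
    rows: list[list[float]] = []
    residues: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            tokens = line.split()
            if len(tokens) < 2:
                continue
            try:
                int(tokens[0])
            except ValueError:
                continue  # header/footer line
            if len(tokens[1]) != 1 or not tokens[1].isalpha():
                continue
            fields = tokens[2:22]
            if len(fields) < 20:
                raise ProfileFormatError(
                    f"{path}:{lineno}: matrix row has {len(fields)} score "
                    "fields, expected 20"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ProfileFormatError(
                    f"{path}:{lineno}: unparseable score field ({exc})"
                ) from None
            residues.append(tokens[1].upper())
    if not rows:
        raise ProfileFormatError(f"{path}: no PSSM matrix rows found")
    return PSSMProfile(
        id=id if id is not None else path.stem,
        scores=np.array(rows, dtype=float),
        normalized=False,
        residues="".join(residues),
    )


def write_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a raw profile in the PSI-BLAST ASCII layout parse_pssm accepts.

    The 20 percentage columns and trailing statistics are filled with zeros;
    they are discarded on parsing, so parse -> write -> parse round-trips
    the score matrix exactly for integer-valued profiles.
    """
    if profile.normalized:
        raise ValueError("write_pssm expects a raw (unnormalized) profile")
    path = Path(path)
    residues = profile.residues or "A" * profile.length
    with open(path, "w") as handle:
        handle.write("\n")
        handle.write(
            "Last position-specific scoring matrix computed, weighted, and "
            "combined pseudocounts\n"
        )
        header = "            " + "   ".join(AA_ORDER) + "   " + "   ".join(AA_ORDER)
        handle.write(header + "\n")
        for i, row in enumerate(profile.scores, start=1):
            scores = " ".join(f"{v:6g}" for v in row)
            pct = " ".join("0" for _ in range(20))
            handle.write(f"{i:5d} {residues[i - 1]} {scores} {pct} 0.00 0.00\n")
        handle.write("\n")
        handle.write("                      K         Lambda\n")


def write_profile_tsv(profile: PSSMProfile, path: str | Path) -> None:
    """Serialize a profile to a simple TSV: id, normalized flag, then rows."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(f"#id\t{profile.id}\n")
        handle.write(f"#normalized\t{int(profile.normalized)}\n")
        if profile.residues:
            handle.write(f"#residues\t{profile.residues}\n")
        for row in profile.scores:
            handle.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_profile_tsv(path: str | Path) -> PSSMProfile:
    """Read a profile written by :func:`write_profile_tsv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key] = value
            else:
                rows.append([float(v) for v in line.split("\t")])
    if not rows:
        raise ProfileFormatError(f"{path}: no profile rows")
    return PSSMProfile(
        id=meta.get("id", path.stem),
        scores=np.array(rows, dtype=float),
        normalized=bool(int(meta.get("normalized", "0"))),
        residues=meta.get("residues") or None,
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_pssm(profile: PSSMProfile) -> PSSMProfile:
    """Map every raw score through the logistic function 1/(1+exp(-x)).

    Output entries lie strictly in (0, 1).  Double normalization is
    forbidden: applying the logistic twice would silently compress the
    profile, so an already-normalized input raises.
    """
    if profile.normalized:
        raise ValueError(
            f"profile {profile.id!r} is already normalized; "
            "double normalization is forbidden"
        )
    with np.errstate(over="ignore"):
        scores = 1.0 / (1.0 + np.exp(-profile.scores))
    # exp underflow can round to exactly 0/1 for |x| > ~37; nudge inside (0,1)
    eps = np.finfo(float).tiny
    scores = np.clip(scores, eps, 1.0 - np.finfo(float).epsneg)
    return replace(profile, scores=scores, normalized=True)


# ---------------------------------------------------------------------------
# Synthetic profiles
# ---------------------------------------------------------------------------

def _apply_transition_bias(scores: np.ndarray, bias: float, rng: np.random.Generator) -> None:
    """Force consecutive rows to share their argmax column with prob ``bias``.

    The forcing swaps the row maximum into the previous row's argmax column,
    which preserves the multiset of values in the row (no marginal shift).
    """
    prev = int(np.argmax(scores[0]))
    for i in range(1, scores.shape[0]):
        if bias > 0.0 and rng.random() < bias:
            j = int(np.argmax(scores[i]))
            if j != prev:
                scores[i, j], scores[i, prev] = scores[i, prev], scores[i, j]
        prev = int(np.argmax(scores[i]))


def simulate_profiles(
    spec: SyntheticDatasetSpec,
) -> tuple[list[PSSMProfile], np.ndarray]:
    """Generate labeled raw profiles with class-dependent structure.

    Raw scores are drawn from a normal distribution (mean 0, sd 3), rounded
    to integers and clipped to [-10, 13], matching the magnitude range of
    real PSI-BLAST log-odds.  Positives additionally receive the
    ``class_shift`` mean offset on ``shifted_columns`` (before rounding) and
    the argmax transition bias.  Bit-reproducible given the seed.

    Returns the profiles (positives first) and the aligned 0/1 label array.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    profiles: list[PSSMProfile] = []
    labels: list[int] = []
    for label, count in ((1, spec.n_positive), (0, spec.n_negative)):
        for idx in range(count):
            length = int(rng.integers(lo, hi + 1))
            scores = rng.normal(loc=0.0, scale=3.0, size=(length, 20))
            if label == 1:
                scores[:, list(spec.shifted_columns)] += spec.class_shift
            scores = np.clip(np.rint(scores), -10, 13)
            if label == 1:
                _apply_transition_bias(scores, spec.transition_bias, rng)
            name = f"{'pos' if label else 'neg'}_{idx:05d}"
            profiles.append(PSSMProfile(id=name, scores=scores, normalized=False))
            labels.append(label)
    return profiles, np.array(labels, dtype=int)


#: Documented (not executed) command template for obtaining real profiles.
PSIBLAST_TEMPLATE = (
    "psiblast -query {fasta} -db nr -num_iterations 3 "
    "-out_ascii_pssm {out_pssm} -evalue 0.001"
)
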