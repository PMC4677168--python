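"""Residue-level input parsing and sliding-window feature encoding.

A prediction target is a single protein chain.  For every residue we hold its
20-column PSSM row (evolutionary conservation, from an iterative PSI-BLAST
search that is run upstream of this package), its predicted relative solvent
accessibility (RSA, percent of maximal exposure), and optionally a binary
interface label.  The feature vector for a residue is the PSSM rows of a
length-``w`` window centred on it, concatenated N-terminal to C-terminal,
followed by the centre residue's RSA — ``20*w + 1`` real values (181 at the
default ``w = 9``).

Windows overhanging a chain terminus are zero-padded so that every residue,
including the termini, yields exactly one feature vector.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: PSI-BLAST ASCII matrix column order of the 20 amino acids.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class ParseError(ValueError):
    """Raised when an input file does not conform to its expected dialect."""


class ChainAssemblyError(ValueError):
    """Raised when per-residue inputs for one chain disagree with each other."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: position, identity, PSSM row, RSA and optional label."""

    chain_id: str
    position: int  # 1-based index along the chain
    amino_acid: str
    pssm_row: np.ndarray  # 20 scores in PSSM_ALPHABET order
    rsa: float  # percent, closed interval [0, 100]
    label: int | None = None  # 1 = interface, 0 = noninterface

    def __post_init__(self) -> None:
        row = np.asarray(self.pssm_row, dtype=float)
        if row.shape != (20,):
            raise ValueError(
                f"pssm_row must have exactly 20 entries, got {row.shape}"
            )
        object.__setattr__(self, "pssm_row", row)
        if not 0.0 <= self.rsa <= 100.0:
            raise ValueError(f"rsa must be in [0, 100], got {self.rsa}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class Chain:
    """An ordered, consecutively numbered list of residues."""

    chain_id: str
    residues: tuple[ResidueRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        for i, r in enumerate(self.residues, start=1):
            if r.position != i:
                raise ValueError(
                    f"chain {self.chain_id}: residue at index {i} has "
                    f"position {r.position}; residues must be numbered 1..L"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def labels(self) -> np.ndarray | None:
        """Label vector, or None if any residue is unlabeled."""
        if any(r.label is None for r in self.residues):
            return None
        return np.array([r.label for r in self.residues], dtype=int)

    @property
    def pssm_matrix(self) -> np.ndarray:
        """(L, 20) array of PSSM rows in residue order."""
        return np.stack([r.pssm_row for r in self.residues])

    @property
    def rsa_values(self) -> np.ndarray:
        return np.array([r.rsa for r in self.residues], dtype=float)


@dataclass(frozen=True)
class FeatureVector:
    """A ``20*w + 1`` window encoding of one residue.

    ``values`` holds the ``w`` PSSM rows flattened N-terminal to C-terminal
    followed by the centre residue's RSA.
    """

    values: np.ndarray
    center_position: int
    chain_id: str
    label: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or (vals.size - 1) % 20 != 0:
            raise ValueError(
                f"feature vector length must be 20*w + 1, got {vals.size}"
            )

    @property
    def window_size(self) -> int:
        return (self.values.size - 1) // 20


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------


def read_pssm(text: str) -> list[tuple[str, np.ndarray]]:
    """Parse a PSI-BLAST ASCII PSSM into per-residue (letter, 20-score) rows.

    The dialect is the ``-out_ascii_pssm`` / ``-Q`` output: header lines, then
    one line per residue starting with the 1-based index and the residue
    letter followed by 20 integer log-odds scores.  Any further columns (the
    weighted-percentage block and information-content columns) are ignored.
    Footer lines (Lambda/K statistics) are skipped.
    """
    rows: list[tuple[str, np.ndarray]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        try:
            int(tokens[0])
        except ValueError:
            continue  # header or footer line
        if len(tokens) < 2 or len(tokens[1]) != 1 or not tokens[1].isalpha():
            raise ParseError(
                f"line {lineno}: residue row must be '<index> <letter> "
                f"<20 scores>': {line.strip()!r}"
            )
        if len(tokens) < 22:
            raise ParseError(
                f"line {lineno}: expected 20 scores after the residue "
                f"letter, found {len(tokens) - 2}"
            )
        try:
            scores = np.array([float(t) for t in tokens[2:22]])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric score: {exc}") from None
        rows.append((tokens[1].upper(), scores))
    if not rows:
        raise ParseError("no residue rows found in PSSM text")
    return rows


def write_pssm(rows: Sequence[tuple[str, np.ndarray]]) -> str:
    """Serialize (letter, scores) rows back to the PSI-BLAST ASCII dialect."""
    out = io.StringIO()
    out.write("\n")
    out.write("Last position-specific scoring matrix computed\n")
    out.write("            " + "   ".join(PSSM_ALPHABET) + "\n")
    for i, (letter, scores) in enumerate(rows, start=1):
        cells = " ".join(f"{int(round(s)):4d}" for s in scores)
        out.write(f"{i:5d} {letter} {cells}\n")
    return out.getvalue()


def _read_position_table(
    text: str, what: str, value_check=None
) -> list[tuple[int, float]]:
    """Shared reader for '<position> [letter] <value>' whitespace tables."""
    seen: set[int] = set()
    out: list[tuple[int, float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens or tokens[0].startswith("#"):
            continue
        if len(tokens) not in (2, 3):
            raise ParseError(
                f"line {lineno}: expected 'position [letter] {what}', "
                f"got {len(tokens)} fields"
            )
        try:
            pos = int(tokens[0])
            value = float(tokens[-1])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric field in {line!r}") from None
        if pos in seen:
            raise ParseError(f"line {lineno}: duplicate position {pos}")
        seen.add(pos)
        if value_check is not None:
            value_check(lineno, value)
        out.append((pos, value))
    return out


def read_rsa(text: str) -> list[tuple[int, float]]:
    """Parse a per-residue RSA table (position, optional letter, percent).

    Values must lie in the closed interval [0, 100]; out-of-range values are
    an error rather than being clamped.
    """

    def check(lineno: int, value: float) -> None:
        if not 0.0 <= value <= 100.0:
            raise ParseError(
                f"line {lineno}: RSA {value} outside [0, 100]"
            )

    return _read_position_table(text, "rsa", check)


def read_labels(text: str) -> list[tuple[int, int]]:
    """Parse a per-residue interface-label table (position, 0/1)."""

    def check(lineno: int, value: float) -> None:
        if value not in (0.0, 1.0):
            raise ParseError(f"line {lineno}: label {value} is not 0 or 1")

    return [(p, int(v)) for p, v in _read_position_table(text, "label", check)]


def read_fasta(text: str) -> dict[str, str]:
    """Parse FASTA text into an id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ParseError("no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# chain assembly
# ---------------------------------------------------------------------------


def _ordered_by_position(
    pairs: Sequence[tuple[int, float]], length: int, what: str, chain_id: str
) -> list[float]:
    by_pos = dict(pairs)
    missing = [p for p in range(1, length + 1) if p not in by_pos]
    if missing or len(by_pos) != length:
        raise ChainAssemblyError(
            f"chain {chain_id}: {what} table has {len(by_pos)} positions "
            f"but the sequence has {length} residues"
            + (f" (missing positions {missing[:5]}...)" if missing else "")
        )
    return [by_pos[p] for p in range(1, length + 1)]


def assemble_chain(
    chain_id: str,
    sequence: str,
    pssm_rows: Sequence[tuple[str, np.ndarray]],
    rsa_values: Sequence[tuple[int, float]] | Sequence[float],
    labels: Sequence[tuple[int, int]] | Sequence[int] | None = None,
) -> Chain:
    """Combine per-residue inputs into a validated :class:`Chain`.

    The FASTA sequence, PSSM row list and RSA table must agree on length, and
    the residue letters of the FASTA sequence must match those recorded in
    the PSSM rows.
    """
    sequence = sequence.upper()
    L = len(sequence)
    n_rsa = len(rsa_values)
    if len(pssm_rows) != L or n_rsa != L:
        raise ChainAssemblyError(
            f"chain {chain_id}: length mismatch — sequence {L}, "
            f"PSSM rows {len(pssm_rows)}, RSA values {n_rsa}"
        )
    if labels is not None and len(labels) != L:
        raise ChainAssemblyError(
            f"chain {chain_id}: {len(labels)} labels for {L} residues"
        )

    mismatches = [
        i + 1
        for i, (seq_aa, (pssm_aa, _)) in enumerate(zip(sequence, pssm_rows))
        if pssm_aa.upper() != seq_aa
    ]
    if mismatches:
        raise ChainAssemblyError(
            f"chain {chain_id}: FASTA and PSSM residue letters differ at "
            f"positions {mismatches}"
        )

    if rsa_values and isinstance(rsa_values[0], tuple):
        rsa_ordered = _ordered_by_position(rsa_values, L, "RSA", chain_id)
    else:
        rsa_ordered = [float(v) for v in rsa_values]

    if labels is None:
        label_ordered: list[int | None] = [None] * L
    elif labels and isinstance(labels[0], tuple):
        label_ordered = [
            int(v) for v in _ordered_by_position(labels, L, "label", chain_id)
        ]
    else:
        label_ordered = [int(v) for v in labels]

    residues = tuple(
        ResidueRecord(
            chain_id=chain_id,
            position=i + 1,
            amino_acid=sequence[i],
            pssm_row=pssm_rows[i][1],
            rsa=rsa_ordered[i],
            label=label_ordered[i],
        )
        for i in range(L)
    )
    return Chain(chain_id=chain_id, residues=residues)


# ---------------------------------------------------------------------------
# window encoding
# ---------------------------------------------------------------------------


def encode_windows(chain: Chain, w: int) -> list[FeatureVector]:
    """Encode every residue of ``chain`` as a ``20*w + 1`` feature vector.

    Each residue is a window centre, termini included; window positions that
    fall outside the chain contribute a 20-zero pad row.  The trailing value
    is the centre residue's RSA, and labels are copied from the centre.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window size must be an odd integer >= 1, got {w}")
    half = (w - 1) // 2
    L = len(chain)
    padded = np.zeros((L + 2 * half, 20))
    padded[half : half + L] = chain.pssm_matrix
    rsa = chain.rsa_values
    vectors = []
    for i, residue in enumerate(chain.residues):
        window = padded[i : i + w].reshape(-1)
        values = np.concatenate([window, [rsa[i]]])
        vectors.append(
            FeatureVector(
                values=values,
                center_position=residue.position,
                chain_id=chain.chain_id,
                label=residue.label,
            )
        )
    return vectors


def encode_dataset(
    chains: Iterable[Chain], w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Encode labeled chains into a design matrix X and label vector y."""
    X_parts, y_parts = [], []
    for chain in chains:
        labels = chain.labels
        if labels is None:
            raise ValueError(f"chain {chain.chain_id} has unlabeled residues")
        X_parts.append(np.stack([fv.values for fv in encode_windows(chain, w)]))
        y_parts.append(labels)
    if not X_parts:
        raise ValueError("no chains to encode")
    return np.concatenate(X_parts), np.concatenate(y_parts)


# ---------------------------------------------------------------------------
# chain-directory persistence (shared by the CLI and the fixture generator)
# ---------------------------------------------------------------------------

FASTA_NAME = "chains.fasta"


def load_chain_dir(directory: str | os.PathLike) -> list[Chain]:
    """Load chains from a directory holding ``chains.fasta`` plus per-chain
    ``<id>.pssm``, ``<id>.rsa`` and optional ``<id>.labels`` files."""
    directory = Path(directory)
    fasta_path = directory / FASTA_NAME
    if not fasta_path.exists():
        raise FileNotFoundError(f"{fasta_path} not found")
    sequences = read_fasta(fasta_path.read_text())
    chains = []
    for chain_id, seq in sequences.items():
        pssm_rows = read_pssm((directory / f"{chain_id}.pssm").read_text())
        rsa_values = read_rsa((directory / f"{chain_id}.rsa").read_text())
        label_path = directory / f"{chain_id}.labels"
        labels = read_labels(label_path.read_text()) if label_path.exists() else None
        chains.append(assemble_chain(chain_id, seq, pssm_rows, rsa_values, labels))
    return chains


def write_chain_dir(chains: Iterable[Chain], directory: str | os.PathLike) -> None:
    """Write chains in the layout :func:`load_chain_dir` reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta_lines = []
    for chain in chains:
        fasta_lines.append(f">{chain.chain_id}\n{chain.sequence}\n")
        rows = [(r.amino_acid, r.pssm_row) for r in chain.residues]
        (directory / f"{chain.chain_id}.pssm").write_text(write_pssm(rows))
        (directory / f"{chain.chain_id}.rsa").write_text(
            "".join(
                f"{r.position}\t{r.amino_acid}\t{r.rsa:.2f}\n"
                for r in chain.residues
            )
        )
        if all(r.label is not None for r in chain.residues):
            (directory / f"{chain.chain_id}.labels").write_text(
                "".join(f"{r.position}\t{r.label}\n" for r in chain.residues)
            )
    (directory / FASTA_NAME).write_text("".join(fasta_lines))
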