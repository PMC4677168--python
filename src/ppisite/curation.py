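"""Rule-based curation of dimeric complexes for a nonredundant benchmark.

The training corpus is built from two-chain (dimeric) crystal structures,
filtered by seven rules applied in order:

1. resolution worse than 3.0 A (strictly above), or either chain shorter
   than 50 residues;
2. homodimers — both chains carry the same UniProt accession;
3. missing ratio (missing residues / sequence length) >= 0.30;
4. transmembrane complexes;
5. interface area outside the inclusive band 500–2500 A^2;
6. complexes that are sub-assemblies of larger complexes (their interfaces
   are ambiguous);
7. sequence redundancy — within each precomputed sequence-identity cluster
   (>25% identity) only the first complex in input order is kept.

Upstream annotation services (structure databases, transmembrane registries,
clustering runs) are consumed as columns of the metadata table; this module
only applies the rules and keeps a per-rule audit trail.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

RULE_IDS = (
    "rule1_resolution_length",
    "rule2_homodimer",
    "rule3_missing_ratio",
    "rule4_transmembrane",
    "rule5_interface_area",
    "rule6_subcomplex",
    "rule7_redundancy",
)

MAX_RESOLUTION = 3.0  # A; strictly above is rejected
MIN_CHAIN_LENGTH = 50  # strictly below is rejected
MAX_MISSING_RATIO = 0.30  # >= is rejected
INTERFACE_AREA_RANGE = (500.0, 2500.0)  # inclusive band


@dataclass(frozen=True)
class ComplexMetadata:
    """Complex-level annotations needed by the curation rules (dimers only)."""

    complex_id: str
    method: str  # experimental method, e.g. "xray"
    resolution: float | None  # A; may be absent for non-X-ray entries
    chain_lengths: tuple[int, int]
    uniprot_accessions: tuple[str, str]
    missing_ratio: float
    is_transmembrane: bool
    interface_area: float
    is_subcomplex: bool
    cluster_ids: tuple[str, str]  # per-chain sequence-identity cluster labels

    def __post_init__(self) -> None:
        if len(self.chain_lengths) != 2 or len(self.uniprot_accessions) != 2:
            raise ValueError(
                f"{self.complex_id}: exactly two chains required (dimer)"
            )
        if len(self.cluster_ids) != 2:
            raise ValueError(f"{self.complex_id}: two per-chain cluster ids required")
        if not 0.0 <= self.missing_ratio <= 1.0:
            raise ValueError(
                f"{self.complex_id}: missing_ratio must be in [0, 1], "
                f"got {self.missing_ratio}"
            )
        if any(l < 1 for l in self.chain_lengths):
            raise ValueError(f"{self.complex_id}: chain lengths must be >= 1")


@dataclass(frozen=True)
class CurationReport:
    retained: tuple[str, ...]
    rejected: tuple[tuple[str, str, str], ...]  # (complex_id, rule_id, reason)

    def __post_init__(self) -> None:
        object.__setattr__(self, "retained", tuple(self.retained))
        object.__setattr__(self, "rejected", tuple(self.rejected))
        kept = set(self.retained)
        gone = {cid for cid, _, _ in self.rejected}
        if kept & gone:
            raise ValueError("retained and rejected sets overlap")


def _first_violation(
    meta: ComplexMetadata, claimed_clusters: set[str]
) -> tuple[str, str] | None:
    """The first rule the complex violates, or None if it passes all seven."""
    if meta.resolution is not None and meta.resolution > MAX_RESOLUTION:
        return RULE_IDS[0], f"resolution {meta.resolution} A > {MAX_RESOLUTION} A"
    if min(meta.chain_lengths) < MIN_CHAIN_LENGTH:
        return (
            RULE_IDS[0],
            f"chain length {min(meta.chain_lengths)} < {MIN_CHAIN_LENGTH}",
        )
    if meta.uniprot_accessions[0] == meta.uniprot_accessions[1]:
        return (
            RULE_IDS[1],
            f"homodimer: both chains are {meta.uniprot_accessions[0]}",
        )
    if meta.missing_ratio >= MAX_MISSING_RATIO:
        return RULE_IDS[2], f"missing ratio {meta.missing_ratio:.2f} >= 0.30"
    if meta.is_transmembrane:
        return RULE_IDS[3], "transmembrane complex"
    lo, hi = INTERFACE_AREA_RANGE
    if not lo <= meta.interface_area <= hi:
        return (
            RULE_IDS[4],
            f"interface area {meta.interface_area} A^2 outside [{lo}, {hi}]",
        )
    if meta.is_subcomplex:
        return RULE_IDS[5], "part of a larger complex"
    dup = [c for c in meta.cluster_ids if c in claimed_clusters]
    if dup:
        return (
            RULE_IDS[6],
            f"cluster {dup[0]} already represented by an earlier complex",
        )
    return None


def apply_filters(metadata: Sequence[ComplexMetadata]) -> CurationReport:
    """Apply the seven rules in order; attribution goes to the first violated.

    Rule 7 keeps the first complex (input order) of each sequence-identity
    cluster; a complex claims its clusters only when it survives rules 1–6.
    """
    ids = [m.complex_id for m in metadata]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate complex_id in metadata")
    retained: list[str] = []
    rejected: list[tuple[str, str, str]] = []
    claimed: set[str] = set()
    for meta in metadata:
        violation = _first_violation(meta, claimed)
        if violation is None:
            retained.append(meta.complex_id)
            claimed.update(meta.cluster_ids)
        else:
            rejected.append((meta.complex_id, *violation))
    return CurationReport(retained=tuple(retained), rejected=tuple(rejected))


def summarize(report: CurationReport) -> dict[str, int]:
    """Per-rule rejection counts plus the retained total."""
    counts = {rule: 0 for rule in RULE_IDS}
    for _, rule, _ in report.rejected:
        counts[rule] += 1
    counts["retained"] = len(report.retained)
    return counts


# ---------------------------------------------------------------------------
# TSV input/output
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = (
    "complex_id",
    "method",
    "resolution",
    "chain1_length",
    "chain2_length",
    "uniprot1",
    "uniprot2",
    "missing_ratio",
    "is_transmembrane",
    "interface_area",
    "is_subcomplex",
    "cluster1",
    "cluster2",
)


def metadata_to_tsv(metadata: Sequence[ComplexMetadata]) -> str:
    out = io.StringIO()
    out.write("\t".join(_METADATA_COLUMNS) + "\n")
    for m in metadata:
        res = "" if m.resolution is None else f"{m.resolution:.2f}"
        out.write(
            "\t".join(
                [
                    m.complex_id,
                    m.method,
                    res,
                    str(m.chain_lengths[0]),
                    str(m.chain_lengths[1]),
                    m.uniprot_accessions[0],
                    m.uniprot_accessions[1],
                    f"{m.missing_ratio:.4f}",
                    str(int(m.is_transmembrane)),
                    f"{m.interface_area:.1f}",
                    str(int(m.is_subcomplex)),
                    m.cluster_ids[0],
                    m.cluster_ids[1],
                ]
            )
            + "\n"
        )
    return out.getvalue()


def metadata_from_tsv(text: str) -> list[ComplexMetadata]:
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise ValueError("empty metadata table")
    header = lines[0].split("\t")
    if tuple(header) != _METADATA_COLUMNS:
        raise ValueError(
            f"unexpected metadata header: {header}; expected {_METADATA_COLUMNS}"
        )
    records = []
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(_METADATA_COLUMNS):
            raise ValueError(
                f"malformed metadata row for "
                f"{cells[0] if cells else '?'}: {len(cells)} columns"
            )
        records.append(
            ComplexMetadata(
                complex_id=cells[0],
                method=cells[1],
                resolution=None if cells[2] == "" else float(cells[2]),
                chain_lengths=(int(cells[3]), int(cells[4])),
                uniprot_accessions=(cells[5], cells[6]),
                missing_ratio=float(cells[7]),
                is_transmembrane=bool(int(cells[8])),
                interface_area=float(cells[9]),
                is_subcomplex=bool(int(cells[10])),
                cluster_ids=(cells[11], cells[12]),
            )
        )
    return records


def report_to_tsv(report: CurationReport) -> str:
    out = io.StringIO()
    out.write("complex_id\tstatus\trule\treason\n")
    for cid in report.retained:
        out.write(f"{cid}\tretained\t\t\n")
    for cid, rule, reason in report.rejected:
        out.write(f"{cid}\trejected\t{rule}\t{reason}\n")
    return out.getvalue()
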