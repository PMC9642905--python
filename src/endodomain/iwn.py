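"""IWN short-linear-motif scanning and BLAST-hit curation.

The motif is a 4-residue window: position 1 in {I, L, V}, position 2 = W,
positions 3-4 in a configurable hydrophilic set (default: polar/charged
S, T, N, Q, D, E, K, R, H).  Unknown residues (X) never match.

Hit tables are screened with strict thresholds (coverage > 40 percent,
e-value < 1e-3) and a subject is called a candidate homolog when it both
survives the screen and carries at least three motif occurrences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DEFAULT_HYDROPHILIC",
    "SequenceRecord",
    "MotifHit",
    "BlastRow",
    "HomologCall",
    "scan_iwn",
    "filter_blast",
    "call_homolog",
    "presence_table",
    "itol_annotation",
]

DEFAULT_HYDROPHILIC = frozenset("STNQDEKRH")
MIN_MOTIFS_FOR_CANDIDATE = 3

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence; residues are upper-cased on construction."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.identifier}: invalid residues {sorted(bad)} "
                "(expected the 20-letter alphabet plus X)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``position`` is the 1-based index of its first residue."""

    position: int
    window: str


@dataclass(frozen=True)
class BlastRow:
    query_id: str
    subject_id: str
    query_coverage_percent: float
    evalue: float
    taxon: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.query_coverage_percent <= 100:
            raise ValueError(
                f"{self.subject_id}: query_coverage_percent must lie in [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError(f"{self.subject_id}: evalue must be non-negative")


@dataclass(frozen=True)
class HomologCall:
    subject_id: str
    n_motifs: int
    passes_blast_filter: bool
    is_candidate: bool
    taxon: str = ""

    def __post_init__(self) -> None:
        expected = self.passes_blast_filter and self.n_motifs >= MIN_MOTIFS_FOR_CANDIDATE
        if self.is_candidate != expected:
            raise ValueError("is_candidate inconsistent with filter flag and motif count")


def scan_iwn(
    seq: SequenceRecord | str,
    hydrophilic: frozenset[str] | set[str] = DEFAULT_HYDROPHILIC,
) -> list[MotifHit]:
    """Report every (possibly overlapping) IWN-pattern 4-mer, in sequence order."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    zeta = "".join(sorted(hydrophilic))
    pattern = re.compile(f"(?=([ILV]W[{re.escape(zeta)}][{re.escape(zeta)}]))")
    return [
        MotifHit(position=m.start() + 1, window=m.group(1))
        for m in pattern.finditer(residues)
    ]


def filter_blast(
    rows: Iterable[BlastRow] | pd.DataFrame,
    min_coverage: float = 40.0,
    max_evalue: float = 1e-3,
):
    """Keep rows with coverage strictly above and e-value strictly below the cutoffs.

    Accepts a list of :class:`BlastRow` (returns a filtered list, order
    preserved) or a DataFrame with ``query_coverage_percent`` and ``evalue``
    columns (returns a filtered DataFrame).
    """
    if isinstance(rows, pd.DataFrame):
        for col in ("query_coverage_percent", "evalue"):
            if col not in rows.columns:
                raise ValueError(f"hit table lacks required column {col!r}")
        keep = (rows["query_coverage_percent"] > min_coverage) & (
            rows["evalue"] < max_evalue
        )
        return rows.loc[keep]
    out = []
    for i, row in enumerate(rows):
        if not isinstance(row, BlastRow):
            raise ValueError(f"malformed row at index {i}: {row!r}")
        if row.query_coverage_percent > min_coverage and row.evalue < max_evalue:
            out.append(row)
    return out


def call_homolog(
    row: BlastRow,
    seq: SequenceRecord,
    min_coverage: float = 40.0,
    max_evalue: float = 1e-3,
    hydrophilic: frozenset[str] | set[str] = DEFAULT_HYDROPHILIC,
) -> HomologCall:
    """Combine the hit-table screen with the >=3-motif curation rule."""
    if row.subject_id != seq.identifier:
        raise ValueError(
            f"subject id mismatch: row has {row.subject_id!r}, "
            f"sequence is {seq.identifier!r}"
        )
    passes = row.query_coverage_percent > min_coverage and row.evalue < max_evalue
    n_motifs = len(scan_iwn(seq, hydrophilic))
    return HomologCall(
        subject_id=row.subject_id,
        n_motifs=n_motifs,
        passes_blast_filter=passes,
        is_candidate=passes and n_motifs >= MIN_MOTIFS_FOR_CANDIDATE,
        taxon=row.taxon,
    )


def presence_table(
    calls: Iterable[HomologCall], taxa: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-taxon candidate counts and presence flags, sorted by taxon.

    ``taxa`` maps subject ids to taxon names; when absent each call's own
    ``taxon`` field is used. Unknown subject ids get a blank taxon (a warning
    is emitted) and their calls are retained.
    """
    import warnings

    rows = []
    for call in calls:
        if taxa is not None:
            taxon = taxa.get(call.subject_id)
            if taxon is None:
                warnings.warn(
                    f"unknown taxon for subject {call.subject_id!r}; keeping row "
                    "with blank taxon",
                    stacklevel=2,
                )
                taxon = ""
        else:
            taxon = call.taxon
        rows.append({"taxon": taxon, "is_candidate": call.is_candidate})
    if not rows:
        return pd.DataFrame(columns=["taxon", "candidate_count", "present"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("taxon", as_index=False)["is_candidate"]
        .sum()
        .rename(columns={"is_candidate": "candidate_count"})
    )
    out["candidate_count"] = out["candidate_count"].astype(int)
    out["present"] = out["candidate_count"] > 0
    return out.sort_values("taxon").reset_index(drop=True)


def itol_annotation(
    table: pd.DataFrame,
    present_color: str = "#ff0000",
    absent_color: str = "#808080",
) -> str:
    """Deterministic iTOL-style branch-coloring text from a presence table."""
    lines = ["DATASET_STYLE", "SEPARATOR TAB", "DATA"]
    for _, row in table.iterrows():
        color = present_color if row["present"] else absent_color
        lines.append(f"{row['taxon']}\tbranch\tnode\t{color}\t1\tnormal")
    return "\n".join(lines) + "\n"
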