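"""Readers, writers and validators for interaction and similarity matrices.

File dialect: tab-separated, first row holds column identifiers (the first
header cell may be empty), first column holds row identifiers.  Interaction
files from the Yamanishi "gold standard" distribution put targets in rows and
drugs in columns; internally the interaction matrix ``Y`` is always oriented
drugs-in-rows, whatever the file orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: absolute asymmetry beyond which a similarity file is rejected rather than
#: repaired by averaging with its transpose
SYMMETRY_TOLERANCE = 1e-6


class DataFormatError(ValueError):
    """Raised for malformed, non-binary, ragged or duplicated input files."""


@dataclass
class DrugTargetNetwork:
    """A bipartite interaction network: drugs, targets and binary labels.

    ``Y[i, j] = 1`` iff drug ``drug_ids[i]`` is known to interact with target
    ``target_ids[j]``; every unlabeled pair is an unknown (negative) sample.
    """

    drug_ids: list[str]
    target_ids: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        m, n = len(self.drug_ids), len(self.target_ids)
        if m < 1 or n < 1:
            raise DataFormatError("need at least one drug and one target")
        if len(set(self.drug_ids)) != m:
            raise DataFormatError("duplicate drug identifiers")
        if len(set(self.target_ids)) != n:
            raise DataFormatError("duplicate target identifiers")
        if self.Y.shape != (m, n):
            raise DataFormatError(
                f"Y has shape {self.Y.shape}, expected ({m}, {n})"
            )
        if not np.isin(self.Y, (0, 1)).all():
            raise DataFormatError("interaction labels must be exactly 0 or 1")
        self.Y = self.Y.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_known(self) -> int:
        """Number of known interactions (ones in Y)."""
        return int(self.Y.sum())

    @property
    def n_unknown(self) -> int:
        """Number of unlabeled pairs, the negative-sample universe."""
        return self.Y.size - self.n_known

    def positive_pairs(self) -> list[tuple[str, str]]:
        """All known interacting (drug_id, target_id) pairs, row-major order."""
        return [
            (self.drug_ids[i], self.target_ids[j])
            for i, j in zip(*np.nonzero(self.Y))
        ]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity scores in [0, 1] for one node family."""

    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise DataFormatError("duplicate identifiers in similarity matrix")
        if self.S.shape != (n, n):
            raise DataFormatError("similarity matrix must be square over ids")
        out_of_range = (self.S < 0) | (self.S > 1)
        if out_of_range.any():
            i, j = np.argwhere(out_of_range)[0]
            raise DataFormatError(
                f"similarity values must lie in [0, 1]; offending entry at "
                f"({self.ids[i]}, {self.ids[j]}) = {self.S[i, j]}"
            )
        asym = np.abs(self.S - self.S.T).max()
        if asym > SYMMETRY_TOLERANCE:
            raise DataFormatError(
                f"similarity matrix asymmetry {asym:g} exceeds tolerance "
                f"{SYMMETRY_TOLERANCE:g}"
            )
        if asym > 0:
            self.S = (self.S + self.S.T) / 2.0
        if not np.allclose(np.diag(self.S), 1.0, atol=1e-9):
            raise DataFormatError("similarity diagonal entries must equal 1")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise DataFormatError(f"{path}: duplicate column identifier")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise DataFormatError(f"{path}: malformed table ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise DataFormatError(f"{path}: duplicate row or column identifier")
    return df


def read_interaction_matrix(
    path: str | Path, orientation: str = "targets_in_rows"
) -> DrugTargetNetwork:
    """Read a binary interaction matrix file.

    Parameters
    ----------
    path:
        Tab-separated matrix with a header of column identifiers and a
        leading column of row identifiers; every cell must parse as 0 or 1.
    orientation:
        ``"targets_in_rows"`` (the Yamanishi distribution convention) or
        ``"drugs_in_rows"``.  The returned network is always drugs-in-rows.
    """
    if orientation not in ("targets_in_rows", "drugs_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = _read_table(path)
    values = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for (i, j), cell in np.ndenumerate(raw):
        text = str(cell).strip()
        if text not in ("0", "1"):
            raise DataFormatError(
                f"{path}: non-binary cell {text!r} at row "
                f"{df.index[i]!r}, column {df.columns[j]!r}"
            )
        values[i, j] = int(text)
    if orientation == "targets_in_rows":
        return DrugTargetNetwork(
            drug_ids=list(df.columns), target_ids=list(df.index), Y=values.T
        )
    return DrugTargetNetwork(
        drug_ids=list(df.index), target_ids=list(df.columns), Y=values
    )


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a square tab-separated similarity matrix.

    Row and column identifier sets must match; small (<= 1e-6) asymmetries
    left by file rounding are repaired by averaging with the transpose.
    """
    df = _read_table(path)
    if list(df.index) != list(df.columns):
        if set(df.index) == set(df.columns):
            df = df.loc[:, list(df.index)]
        else:
            raise DataFormatError(
                f"{path}: row and column identifier sets differ"
            )
    try:
        S = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-numeric similarity cell ({exc})")
    return SimilarityMatrix(ids=list(df.index), S=S)


def write_interaction_matrix(
    net: DrugTargetNetwork,
    path: str | Path,
    orientation: str = "targets_in_rows",
) -> None:
    """Write the interaction matrix in the tab-separated file dialect."""
    df = pd.DataFrame(net.Y, index=net.drug_ids, columns=net.target_ids)
    if orientation == "targets_in_rows":
        df = df.T
    elif orientation != "drugs_in_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    df.to_csv(path, sep="\t")


def write_similarity_matrix(
    sim: SimilarityMatrix, path: str | Path, precision: int = 9
) -> None:
    df = pd.DataFrame(sim.S, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep="\t", float_format=f"%.{precision}g")


def write_predictions(
    rows: list[tuple[int, str, str, float]], path: str | Path
) -> None:
    """Write ranked predictions as (rank, drug_id, target_id, score) TSV."""
    with open(path, "w") as fh:
        fh.write("rank\tdrug_id\ttarget_id\tscore\n")
        for rank, drug, target, score in rows:
            fh.write(f"{rank}\t{drug}\t{target}\t{score:.6f}\n")


@dataclass
class ValidationReport:
    """Report-only dataset consistency check; never raises."""

    drug_id_mismatches: list[str] = field(default_factory=list)
    target_id_mismatches: list[str] = field(default_factory=list)
    drugs_without_interactions: list[str] = field(default_factory=list)
    targets_without_interactions: list[str] = field(default_factory=list)

    @property
    def issues(self) -> list[str]:
        out = []
        for d in self.drug_id_mismatches:
            out.append(f"drug identifier mismatch: {d}")
        for t in self.target_id_mismatches:
            out.append(f"target identifier mismatch: {t}")
        for d in self.drugs_without_interactions:
            out.append(f"drug {d} has no known interaction")
        for t in self.targets_without_interactions:
            out.append(f"target {t} has no known interaction")
        return out

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(
    net: DrugTargetNetwork, dd: SimilarityMatrix, tt: SimilarityMatrix
) -> ValidationReport:
    """Cross-check identifier alignment and per-node interaction coverage.

    Drugs or targets with zero known interactions violate the random CV
    setting's requirement that every node is seen in training; they are
    reported, not removed.
    """
    report = ValidationReport()
    report.drug_id_mismatches = sorted(set(net.drug_ids) ^ set(dd.ids))
    report.target_id_mismatches = sorted(set(net.target_ids) ^ set(tt.ids))
    row_sums = net.Y.sum(axis=1)
    col_sums = net.Y.sum(axis=0)
    report.drugs_without_interactions = [
        d for d, s in zip(net.drug_ids, row_sums) if s == 0
    ]
    report.targets_without_interactions = [
        t for t, s in zip(net.target_ids, col_sums) if s == 0
    ]
    if not report.ok:
        logger.warning("dataset validation found %d issues", len(report.issues))
    return report
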