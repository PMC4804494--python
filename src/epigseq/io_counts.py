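"""Reading, validation and writing of the tab-delimited count format.

The input is a tab-delimited text file:

* row 1 — a header cell followed by one group label per sample (one group is
  the control/baseline, the study should span at least 4 groups);
* row 2 — a header cell followed by the total mapped reads of each sample;
* remaining rows — a unique gene ID followed by non-negative integer read
  counts.

Counts are analysed raw; reads-per-million (RPM) ratios are computed only for
visualisation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "RatioMatrix",
    "CountFormatError",
    "read_counts",
    "write_counts",
    "log2_rpm_ratio",
    "write_gene_table",
    "write_pattern_summary",
    "read_gene_table",
]


class CountFormatError(ValueError):
    """Malformed count file or invalid count-matrix content."""


@dataclass
class CountMatrix:
    """Genes x samples read counts with group labels and library sizes.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    counts : ndarray of int, shape (n_genes, n_samples)
        Non-negative raw read counts.
    group_labels : list of str
        One group label per sample column.
    control_label : str
        The label designating the control/baseline group.
    library_sizes : ndarray of int, shape (n_samples,)
        Total mapped reads per sample (file row 2), all positive.
    """

    gene_ids: list
    counts: np.ndarray
    group_labels: list
    control_label: str
    library_sizes: np.ndarray
    allow_few_groups: bool = False
    #: genes whose counts are zero in every sample; retained in the matrix but
    #: excluded from every statistic downstream.
    all_zero: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes)
        self.gene_ids = list(self.gene_ids)
        self.group_labels = list(self.group_labels)
        self._validate()
        self.all_zero = (self.counts == 0).all(axis=1)

    # -- validation -----------------------------------------------------
    def _validate(self):
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise CountFormatError("gene_ids length does not match count rows")
        if len(self.group_labels) != n_samples:
            raise CountFormatError(
                f"{len(self.group_labels)} group labels for {n_samples} count columns"
            )
        if self.library_sizes.shape != (n_samples,):
            raise CountFormatError("one library size per sample is required")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(np.mod(self.counts, 1) != 0) or np.any(~np.isfinite(self.counts.astype(float))):
                raise CountFormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise CountFormatError(
                f"negative count for gene {self.gene_ids[g]!r} in sample column {s + 1}"
            )
        bad = np.where(self.library_sizes <= 0)[0]
        if bad.size:
            raise CountFormatError(
                f"library size must be positive; sample column {bad[0] + 1} has "
                f"{self.library_sizes[bad[0]]}"
            )
        seen, dupes = set(), []
        for gid in self.gene_ids:
            if gid in seen:
                dupes.append(gid)
            seen.add(gid)
        if dupes:
            raise CountFormatError(f"duplicate gene ID {dupes[0]!r}")
        groups = self.group_names()
        if self.control_label not in groups:
            raise CountFormatError(
                f"control label {self.control_label!r} not among groups {groups}"
            )
        for g in groups:
            n = self.group_labels.count(g)
            if n < 2:
                raise CountFormatError(f"group {g!r} has {n} sample(s); at least 2 required")
        if len(groups) < 4 and not self.allow_few_groups:
            raise CountFormatError(
                f"{len(groups)} distinct groups; at least 4 required "
                "(pass allow_few_groups=True to override)"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_names(self) -> list:
        """Distinct group labels in order of first appearance."""
        out = []
        for g in self.group_labels:
            if g not in out:
                out.append(g)
        return out

    def treated_groups(self) -> list:
        """Non-control groups, in order of first appearance."""
        return [g for g in self.group_names() if g != self.control_label]

    def group_columns(self, group: str) -> np.ndarray:
        """Sample-column indices belonging to ``group``."""
        return np.array([j for j, g in enumerate(self.group_labels) if g == group])

    def rpm(self) -> np.ndarray:
        """Reads-per-million matrix (float)."""
        return 1e6 * self.counts / self.library_sizes.astype(float)

    def analyzable(self) -> np.ndarray:
        """Indices of genes entering the analysis (counts not all zero)."""
        return np.where(~self.all_zero)[0]


@dataclass(frozen=True)
class RatioMatrix:
    """log2 RPM ratios to the control-group mean, used for visualisation."""

    values: np.ndarray
    gene_ids: list
    group_labels: list
    pseudocount: float


def read_counts(path, control_label: str, allow_few_groups: bool = False) -> CountMatrix:
    """Read and validate a count file in the tab-delimited input format.

    Errors identify the offending row or column; genes with zero counts in
    every sample are retained but flagged (``CountMatrix.all_zero``) and take
    no part in any downstream statistic.
    """
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
        sizes_line = fh.readline().rstrip("\n").rstrip("\r")
        if not header or not sizes_line:
            raise CountFormatError("file must start with a group-label row and a total-reads row")
        group_labels = header.split("\t")[1:]
        if not group_labels:
            raise CountFormatError("row 1 has no group labels after the first column")
        size_cells = sizes_line.split("\t")[1:]
        if len(size_cells) != len(group_labels):
            raise CountFormatError(
                f"row 2 has {len(size_cells)} totals for {len(group_labels)} samples"
            )
        try:
            library_sizes = np.array([int(c) for c in size_cells])
        except ValueError as exc:
            raise CountFormatError(f"row 2 (total mapped reads) is not integer: {exc}") from exc
        body = fh.read()
    if not body.strip():
        raise CountFormatError("no gene rows found after the two header rows")
    table = pd.read_csv(
        io.StringIO(body), sep="\t", header=None, index_col=0, dtype=str,
    )
    if table.shape[1] != len(group_labels):
        raise CountFormatError(
            f"gene rows have {table.shape[1]} columns but row 1 lists "
            f"{len(group_labels)} samples"
        )
    gene_ids = [str(g) for g in table.index]
    try:
        counts = table.to_numpy(dtype=float)
    except ValueError as exc:
        raise CountFormatError(f"non-numeric count value: {exc}") from exc
    frac = np.mod(counts, 1) != 0
    if frac.any():
        g, s = np.argwhere(frac)[0]
        raise CountFormatError(
            f"non-integer count {counts[g, s]} for gene {gene_ids[g]!r} "
            f"in sample column {s + 1}"
        )
    return CountMatrix(
        gene_ids=gene_ids,
        counts=counts.astype(np.int64),
        group_labels=group_labels,
        control_label=control_label,
        library_sizes=library_sizes,
        allow_few_groups=allow_few_groups,
    )


def write_counts(cm: CountMatrix, path) -> None:
    """Write a CountMatrix back to the tab-delimited input format (LF endings)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("GeneID\t" + "\t".join(cm.group_labels) + "\n")
        fh.write("TotalMappedReads\t" + "\t".join(str(int(s)) for s in cm.library_sizes) + "\n")
        for gid, row in zip(cm.gene_ids, cm.counts):
            fh.write(str(gid) + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def log2_rpm_ratio(cm: CountMatrix, pseudocount: float = 1.0) -> RatioMatrix:
    """log2 of each sample's RPM over the gene's mean control RPM.

    ``value_ij = log2((RPM_ij + pseudocount) / (mean control RPM_i + pseudocount))``.
    A positive pseudocount guarantees finite values for zero counts.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    rpm = cm.rpm()
    ctrl = cm.group_columns(cm.control_label)
    ctrl_mean = rpm[:, ctrl].mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2((rpm + pseudocount) / (ctrl_mean + pseudocount))
    return RatioMatrix(values=values, gene_ids=list(cm.gene_ids),
                       group_labels=list(cm.group_labels), pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def gene_table_frame(result, stats, cm: CountMatrix) -> pd.DataFrame:
    """Per-clustered-gene table: pattern, CY_s to the representative, per-group
    magnitudes, dispersion and GLM p-values (raw and BH-adjusted)."""
    from statsmodels.stats.multitest import multipletests

    groups = cm.treated_groups()
    rows = []
    for cl in result.clusters:
        for g in cl.members:
            rows.append(
                {
                    "gene_id": cm.gene_ids[g],
                    "pattern": cl.number,
                    "cy_to_representative": result.cy_to_representative[g],
                    **{f"magnitude_{grp}": stats.magnitudes[g, k] for k, grp in enumerate(groups)},
                    "dispersion": stats.dispersion[g],
                    "p_value": stats.p_value[g],
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "pattern", "cy_to_representative"]
        + [f"magnitude_{grp}" for grp in groups]
        + ["dispersion", "p_value"],
    )
    if len(df):
        ok = df["p_value"].notna()
        adj = np.full(len(df), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
        df["p_adj_bh"] = adj
        df = df.sort_values(
            ["pattern", "cy_to_representative"], ascending=[True, False], kind="mergesort"
        ).reset_index(drop=True)
    else:
        df["p_adj_bh"] = pd.Series(dtype=float)
    return df


def write_gene_table(result, stats, cm: CountMatrix, path) -> pd.DataFrame:
    """Write the per-gene result table (tab-delimited); returns the frame."""
    df = gene_table_frame(result, stats, cm)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return df


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def pattern_summary_frame(result, cm: CountMatrix) -> pd.DataFrame:
    rows = [
        {
            "pattern": cl.number,
            "representative_gene": cm.gene_ids[cl.representative],
            "n_genes": len(cl.members),
            "pcs": cl.pcs,
            "bootstrap_p": cl.bootstrap_p,
        }
        for cl in result.clusters
    ]
    return pd.DataFrame(
        rows, columns=["pattern", "representative_gene", "n_genes", "pcs", "bootstrap_p"]
    )


def write_pattern_summary(result, cm: CountMatrix, path) -> pd.DataFrame:
    """Write the one-row-per-pattern summary (tab-delimited); returns the frame."""
    df = pattern_summary_frame(result, cm)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return df
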