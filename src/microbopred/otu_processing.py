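"""OTU-table I/O, filtering, and cumulative-sum-scaling (CSS) normalization.

The feature unit throughout is the OTU (operational taxonomic unit, a 16S
sequence cluster).  Tables are stored samples x OTUs.  Raw counts move
through three stages: ``raw_counts`` -> ``filtered`` (doubleton and
prevalence/abundance filters) -> ``css`` (CSS-normalized abundances).

CSS normalization (Paulson et al.) divides each sample's counts by the
cumulative sum of its counts up to a chosen quantile of the positive-count
distribution, then multiplies by a common scale constant.  It damps the
influence of a few very deeply sampled taxa relative to total-sum scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "OTUTable",
    "OTUTableError",
    "read_otu_table",
    "read_biom_json",
    "read_tree",
    "read_taxonomy",
    "remove_doubletons",
    "filter_prevalence_abundance",
    "css_normalize",
    "choose_css_quantile",
    "cage_average_impute",
]

STAGES = ("raw_counts", "filtered", "css")


class OTUTableError(ValueError):
    pass


@dataclass
class OTUTable:
    """A samples x OTUs abundance table with a processing-stage tag.

    ``data`` is a DataFrame indexed by sample (animal) id with OTU-id
    columns.  Stages ``raw_counts`` and ``filtered`` hold non-negative
    integers; ``css`` holds non-negative reals.  ``taxonomy`` optionally
    maps OTU id to a ranked lineage string.
    """

    data: pd.DataFrame = field(repr=False)
    stage: str = "raw_counts"
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise OTUTableError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise OTUTableError(f"duplicate sample ids: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise OTUTableError(f"duplicate OTU ids: {dup}")
        vals = self.data.to_numpy()
        if (vals < 0).any():
            bad = self.data.index[(vals < 0).any(axis=1)].tolist()
            raise OTUTableError(f"negative values in samples {bad}")
        if self.stage in ("raw_counts", "filtered") and not np.allclose(vals, np.round(vals)):
            raise OTUTableError(f"stage {self.stage!r} requires integer counts")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def write(self, path: str | Path) -> None:
        """Write as TSV, samples in rows, with a ``sample_id`` index header."""
        self.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_otu_table(
    path: str | Path,
    orientation: str = "samples_rows",
    stage: str = "raw_counts",
    taxonomy: dict[str, str] | None = None,
) -> OTUTable:
    """Read a TSV OTU table.

    Parameters
    ----------
    orientation
        ``"samples_rows"`` (default) or ``"otus_rows"``; the latter is
        transposed so that the returned table is always samples x OTUs.
    stage
        Stage tag to assign (the file itself does not record it).
    """
    if orientation not in ("samples_rows", "otus_rows"):
        raise OTUTableError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise OTUTableError(f"non-numeric columns: {list(bad)}")
    if orientation == "otus_rows":
        df = df.T
    return OTUTable(df, stage=stage, taxonomy=taxonomy)


def read_biom_json(path: str | Path, stage: str = "raw_counts") -> OTUTable:
    """Read a BIOM v1 (JSON) table into samples x OTUs orientation."""
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(otu_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"])
    df = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    taxonomy = None
    if doc["rows"] and doc["rows"][0].get("metadata") and "taxonomy" in doc["rows"][0]["metadata"]:
        taxonomy = {
            r["id"]: "; ".join(r["metadata"]["taxonomy"])
            for r in doc["rows"]
            if r.get("metadata")
        }
    return OTUTable(df, stage=stage, taxonomy=taxonomy)


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree of OTUs; leaf names must be unique."""
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise OTUTableError("tree has duplicate leaf labels")
    return tree


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (otu_id, lineage) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"], dtype=str)
    return dict(zip(df["otu_id"], df["lineage"]))


def remove_doubletons(table: OTUTable) -> OTUTable:
    """Drop OTUs whose total count across all samples is <= 2.

    This removes singletons and doubletons: OTUs supported by at most two
    reads in the whole study, the usual suspects for sequencing artifacts.
    """
    if table.stage != "raw_counts":
        raise OTUTableError("doubleton removal applies to raw counts")
    keep = table.data.sum(axis=0) > 2
    return replace(table, data=table.data.loc[:, keep])


def filter_prevalence_abundance(
    table: OTUTable,
    min_prevalence: float = 0.05,
    min_rel_abundance: float = 1e-4,
) -> OTUTable:
    """Keep OTUs detected in >= ``min_prevalence`` of samples whose total
    count exceeds ``min_rel_abundance`` of the table's grand total.

    The prevalence cut uses the ceiling (an OTU must be non-zero in at least
    ``ceil(min_prevalence * n_samples)`` samples); the abundance cut is
    strict (share of grand total must exceed the threshold).
    """
    if table.shape[0] == 0:
        raise OTUTableError("empty table")
    vals = table.values()
    n_min = int(np.ceil(min_prevalence * vals.shape[0]))
    prevalent = (vals > 0).sum(axis=0) >= n_min
    total = vals.sum()
    abundant = vals.sum(axis=0) / total > min_rel_abundance
    keep = prevalent & abundant
    stage = "filtered" if table.stage in ("raw_counts", "filtered") else table.stage
    return replace(table, data=table.data.loc[:, keep], stage=stage)


def choose_css_quantile(
    counts: np.ndarray,
    grid: np.ndarray | None = None,
    instability_threshold: float = 0.1,
    fallback: float = 0.5,
) -> float:
    """Data-driven CSS quantile by a relative-instability rule.

    For each candidate quantile l, let ``d_l`` be the median across samples
    of |q_i(l) - qbar(l)|, where q_i is sample i's positive-count quantile
    function and qbar the across-sample mean quantile function.  The chosen
    quantile is the smallest l at which d_l jumps by more than
    ``instability_threshold`` relative to the previous grid point — the
    point where sample depth profiles start to diverge.  Falls back to
    ``fallback`` when no jump is found or the statistic degenerates.
    """
    if grid is None:
        grid = np.arange(0.05, 0.96, 0.01)
    pos = [row[row > 0] for row in counts]
    if any(len(p) == 0 for p in pos):
        raise OTUTableError("sample with all-zero counts")
    q = np.stack([np.quantile(p, grid) for p in pos])  # samples x grid
    ref = q.mean(axis=0)
    d = np.median(np.abs(q - ref), axis=0)
    for k in range(1, len(grid)):
        if d[k - 1] > 0 and (d[k] - d[k - 1]) / d[k - 1] > instability_threshold:
            return float(grid[k])
    return fallback


def css_normalize(
    table: OTUTable,
    scaling_quantile: float | None = None,
    scale_constant: float = 1000.0,
) -> OTUTable:
    """CSS-normalize a count table.

    Each sample i is scaled by ``s_i`` = the sum of its counts that are <=
    its own ``scaling_quantile`` quantile of positive counts, then
    multiplied by ``scale_constant``::

        value(i, j) = count(i, j) / s_i * scale_constant

    With ``scaling_quantile=None`` the quantile is chosen from the data by
    :func:`choose_css_quantile`.

    Raises
    ------
    OTUTableError
        If a sample has no positive counts (its scale is undefined).
    """
    if table.stage not in ("raw_counts", "filtered"):
        raise OTUTableError("CSS applies to count-stage tables")
    counts = table.values()
    zero = counts.sum(axis=1) == 0
    if zero.any():
        bad = [sid for sid, z in zip(table.sample_ids, zero) if z]
        raise OTUTableError(f"samples with all-zero counts: {bad}")
    if scaling_quantile is None:
        scaling_quantile = choose_css_quantile(counts)
    s = np.empty(counts.shape[0])
    for i, row in enumerate(counts):
        pos = row[row > 0]
        qv = np.quantile(pos, scaling_quantile)
        s[i] = row[row <= qv].sum()
    if (s <= 0).any():
        bad = [sid for sid, v in zip(table.sample_ids, s) if v <= 0]
        raise OTUTableError(f"zero CSS scale for samples: {bad}")
    norm = counts / s[:, None] * scale_constant
    df = pd.DataFrame(norm, index=table.data.index, columns=table.data.columns)
    return replace(table, data=df, stage="css")


def cage_average_impute(css_table: OTUTable, design: pd.DataFrame) -> OTUTable:
    """Extend a CSS table to all animals, imputing unassessed cage mates.

    Animals present in ``css_table`` keep their rows; every other animal in
    ``design`` receives the arithmetic mean of its assessed cage mates' CSS
    rows.  ``design`` needs columns ``animal`` and ``cage``.

    Raises
    ------
    OTUTableError
        If some cage has no assessed animal (nothing to average).
    """
    if css_table.stage != "css":
        raise OTUTableError("imputation expects a CSS-stage table")
    assessed = set(css_table.sample_ids)
    cages = design.groupby("cage")["animal"].apply(list)
    empty = [c for c, members in cages.items() if not assessed.intersection(members)]
    if empty:
        raise OTUTableError(f"cages with no assessed animal: {empty}")
    rows = {}
    for cage, members in cages.items():
        have = [a for a in members if a in assessed]
        mean_row = css_table.data.loc[have].mean(axis=0)
        for a in members:
            rows[a] = css_table.data.loc[a] if a in assessed else mean_row
    df = pd.DataFrame(rows).T
    df.index.name = css_table.data.index.name
    # keep assessed animals bit-identical, others in design order
    order = [a for a in design["animal"] if a in rows]
    return replace(css_table, data=df.loc[order])
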