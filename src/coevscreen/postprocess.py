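"""Post-run processing: FDR correction, the per-pair chi-squared test,
result filtering, and the two summary tables / network export.

The screen produces one row per detected coevolving residue pair
(the residue table) and one row per protein pair including zero-hit pairs
(the pair table).  Benjamini–Hochberg adjustment is applied once across all
residue-pair p-values (the whole screen is one testing family; per-pair
families are available by flag).  The chi-squared statistic asks, per
protein pair, whether its hit count exceeds the expectation under the
pooled hit rate of the whole run:  ``p_hat = sum(hits) / sum(comparisons)``,
``E = comparisons * p_hat``, ``chi2 = (hits - E)**2 / E`` with one degree of
freedom.  Final result filters mirror the screen's reporting conventions:
strict ``p < p_max``, both columns inside good alignment blocks, both gap
fractions strictly below the cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from coevscreen.caps_engine import BIDIRECTIONAL_COLUMNS, ScanLog

__all__ = [
    "ResultTables",
    "PAIR_COLUMNS",
    "bh_fdr",
    "build_tables",
    "chisq_pairs",
    "filter_results",
    "export_network",
    "write_tables",
]

PAIR_COLUMNS = [
    "pair_id",
    "protein_a",
    "protein_b",
    "n_hits",
    "n_comparisons",
    "chi2",
    "chi2_p",
    "min_q",
]

RESIDUE_COLUMNS = BIDIRECTIONAL_COLUMNS + ["q"]


@dataclass
class ResultTables:
    """The two output spreadsheets of a screen.

    ``residue_table``: every reported coevolving residue pair across all
    protein pairs.  ``pair_table``: one row per analysed protein pair,
    including pairs with zero hits.
    """

    residue_table: pd.DataFrame
    pair_table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.residue_table.pair_id) - set(self.pair_table.pair_id)
        if missing:
            raise ValueError(
                f"residue table references pairs absent from pair table: "
                f"{sorted(missing)}"
            )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Input p-values must lie in (0, 1]; the output is monotone in p, at
    least p, and at most 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_tables(
    hit_frames: list[pd.DataFrame],
    logs: list[ScanLog],
    per_pair_fdr: bool = False,
) -> ResultTables:
    """Assemble the residue and pair tables from per-pair scan output.

    ``logs`` must contain the forward-run log of every analysed pair (it
    supplies the comparison counts, including for zero-hit pairs).  BH
    adjustment is applied across all residue rows pooled (or per pair with
    ``per_pair_fdr``), then the chi-squared test is filled in.
    """
    frames = [f for f in hit_frames if len(f)]
    if frames:
        residue = pd.concat(frames, ignore_index=True)
    else:
        residue = pd.DataFrame(columns=BIDIRECTIONAL_COLUMNS)
    residue = residue.sort_values(
        ["pair_id", "site_a", "site_b"], kind="mergesort"
    ).reset_index(drop=True)
    if len(residue):
        if per_pair_fdr:
            residue["q"] = residue.groupby("pair_id")["p"].transform(
                lambda s: bh_fdr(s.to_numpy())
            )
        else:
            residue["q"] = bh_fdr(residue["p"].to_numpy())
    else:
        residue["q"] = pd.Series(dtype=float)

    fwd = {}
    for log in logs:
        if log.direction == "fwd":
            fwd[log.pair_id] = log
    rows = []
    hits_by_pair = residue.groupby("pair_id").size() if len(residue) else {}
    minq_by_pair = residue.groupby("pair_id")["q"].min() if len(residue) else {}
    proteins_by_pair = {}
    if len(residue):
        proteins_by_pair = (
            residue.groupby("pair_id")[["protein_a", "protein_b"]]
            .first()
            .to_dict("index")
        )
    for pid in sorted(fwd):
        log = fwd[pid]
        if pid in proteins_by_pair:
            pa = proteins_by_pair[pid]["protein_a"]
            pb = proteins_by_pair[pid]["protein_b"]
        else:
            pa, _, pb = pid.partition("__")
        rows.append(
            {
                "pair_id": pid,
                "protein_a": pa,
                "protein_b": pb,
                "n_hits": int(hits_by_pair.get(pid, 0)) if len(residue) else 0,
                "n_comparisons": log.n_comparisons,
                "chi2": 0.0,
                "chi2_p": 1.0,
                "min_q": float(minq_by_pair.get(pid, np.nan))
                if len(residue)
                else np.nan,
            }
        )
    pair_table = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    tables = ResultTables(residue, pair_table)
    if len(pair_table) >= 2:
        tables = chisq_pairs(tables)
    return tables


def chisq_pairs(tables: ResultTables) -> ResultTables:
    """Fill the per-pair chi-squared statistic against the pooled hit rate.

    ``p_hat`` pools hits over comparisons across all pairs; each pair's
    expected count is ``E = n_comparisons * p_hat`` and
    ``chi2 = (n_hits - E)**2 / E`` (zero when E is zero), with the upper
    tail of the 1-df chi-squared distribution as ``chi2_p``.
    """
    pair = tables.pair_table.copy()
    if len(pair) < 2 or (pair.n_comparisons > 0).sum() < 2:
        raise ValueError("chi-squared test needs >= 2 pairs with comparisons")
    total_hits = pair.n_hits.sum()
    total_comp = pair.n_comparisons.sum()
    if total_hits == 0:
        warnings.warn("no hits anywhere: all chi2 set to 0", stacklevel=2)
        pair["chi2"] = 0.0
        pair["chi2_p"] = 1.0
        return ResultTables(tables.residue_table, pair)
    p_hat = total_hits / total_comp
    expected = pair.n_comparisons * p_hat
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(expected > 0, (pair.n_hits - expected) ** 2 / expected, 0.0)
    pair["chi2"] = chi2
    pair["chi2_p"] = sps.chi2.sf(chi2, df=1)
    return ResultTables(tables.residue_table, pair)


def filter_results(
    tables: ResultTables,
    p_max: float = 0.005,
    require_good: bool = True,
    gap_max: float = 0.20,
) -> ResultTables:
    """Apply the final reporting filters to the residue table.

    A row survives iff ``p < p_max``, both good-block flags are set (when
    ``require_good``), and both gap fractions are strictly below
    ``gap_max``.  The pair table is recomputed from the surviving rows
    (comparison counts are retained; the chi-squared test is re-run on the
    filtered counts).  The operation is idempotent.
    """
    residue = tables.residue_table
    if len(residue):
        keep = residue.p < p_max
        keep &= (residue.gap_frac_a < gap_max) & (residue.gap_frac_b < gap_max)
        if require_good:
            keep &= residue.good_a & residue.good_b
        residue = residue[keep].reset_index(drop=True)
    pair = tables.pair_table.copy()
    counts = residue.groupby("pair_id").size() if len(residue) else {}
    minq = residue.groupby("pair_id")["q"].min() if len(residue) else {}
    pair["n_hits"] = [int(counts.get(p, 0)) if len(residue) else 0 for p in pair.pair_id]
    pair["min_q"] = [
        float(minq.get(p, np.nan)) if len(residue) else np.nan for p in pair.pair_id
    ]
    out = ResultTables(residue, pair)
    if len(pair) >= 2 and (pair.n_comparisons > 0).sum() >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = chisq_pairs(out)
    return out


def export_network(tables: ResultTables, out_dir: str | Path) -> tuple[Path, Path]:
    """Write Cytoscape-importable edge and node tables.

    Edges: one row per protein pair with at least one residue hit.  Nodes:
    every protein on such an edge, with its degree and summed hit count.
    Output is deterministic (sorted rows, fixed float format).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    residue = tables.residue_table
    pair = tables.pair_table
    edges = pair[pair.n_hits >= 1].copy()
    if len(residue):
        agg = residue.groupby("pair_id")["p"].min()
        edges["min_p"] = [float(agg.get(p, np.nan)) for p in edges.pair_id]
    else:
        edges["min_p"] = np.nan
    edges = edges.rename(columns={"protein_a": "source", "protein_b": "target"})
    edges = edges[
        ["source", "target", "n_hits", "min_p", "min_q", "chi2", "chi2_p"]
    ].sort_values(["source", "target"], kind="mergesort")

    nodes: dict[str, dict] = {}
    for _, row in edges.iterrows():
        for prot in (row.source, row.target):
            rec = nodes.setdefault(prot, {"protein": prot, "degree": 0, "n_hits": 0})
            rec["degree"] += 1
            rec["n_hits"] += int(row.n_hits)
    node_df = pd.DataFrame(
        sorted(nodes.values(), key=lambda r: r["protein"]),
        columns=["protein", "degree", "n_hits"],
    )
    edge_path = out_dir / "edges.tsv"
    node_path = out_dir / "nodes.tsv"
    edges.to_csv(edge_path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    node_df.to_csv(node_path, sep="\t", index=False, lineterminator="\n")
    return edge_path, node_path


def write_tables(tables: ResultTables, out_dir: str | Path) -> dict[str, Path]:
    """Write the residue and pair tables as TSV and CSV spreadsheets."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("residue_table", tables.residue_table),
        ("pair_table", tables.pair_table),
    ):
        for ext, sep in (("tsv", "\t"), ("csv", ",")):
            path = out_dir / f"{name}.{ext}"
            df.to_csv(path, sep=sep, index=False, float_format="%.6g", lineterminator="\n")
            paths[f"{name}.{ext}"] = path
    return paths
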