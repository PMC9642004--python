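"""Collation of per-residue metrics into flagged, spatially clustered issues.

Per-residue score tables and geometry flags are outer-joined on the residue
key, thresholded into boolean flags, and flagged residues are grouped by
single-linkage clustering on CA-CA distance.  Clusters are ranked by
severity (total flag count, then distinct-metric count) so the worst
structural neighbourhoods surface first.  Also provides before/after model
comparison (dFSC / dMolProbity) and contact listing at a residue site.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .fit_scores import GlobalFit, KEY_COLUMNS
from .geometry_validation import GeometrySummary
from .geometry_validation.refdata import vdw_radius
from .structure_map_io import AtomicModel

__all__ = [
    "IssueCluster",
    "ModelComparison",
    "Contact",
    "DEFAULT_THRESHOLDS",
    "flag_residues",
    "cluster_issues",
    "compare_models",
    "contacts_at_site",
    "build_report",
]

#: metric -> below-threshold rule for flagging (half-scale convention)
DEFAULT_THRESHOLDS = {"smoc": 0.5, "fdr_backbone": 0.5}

#: geometry columns flagged directly when true / equal to "outlier"
GEOMETRY_FLAG_COLUMNS = ("rotamer_outlier", "cablam_outlier")

DEFAULT_CLUSTER_CUTOFF = 8.0
DEFAULT_CONTACT_CUTOFF = 4.0
_POLAR_ELEMENTS = {"N", "O"}


@dataclass
class IssueCluster:
    members: list[tuple[str, int, str]]   # (chain, resnum, icode)
    centroid: tuple[float, float, float]  # mean member CA position, A
    severity: int                         # sum of member issue counts
    metrics: list[str]                    # distinct flagged metrics

    @property
    def distinct_metric_count(self) -> int:
        return len(self.metrics)


@dataclass
class ModelComparison:
    """Differences after - before; positive dFSC = better fit, positive
    dMolProbity = worse geometry."""

    dfsc: float
    dmolprobity: float


@dataclass
class Contact:
    site: str
    partner: str
    partner_chain: str
    min_distance: float
    contact_type: str  # polar | nonpolar | clash


def flag_residues(
    tables: list[pd.DataFrame],
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Outer-join per-residue tables and apply per-metric flag rules.

    Score metrics listed in ``thresholds`` are flagged when strictly below
    their threshold; boolean geometry columns are flagged directly.  Null
    scores are never flagged.  Duplicate residue keys within one table are
    an error naming the residue.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    merged: pd.DataFrame | None = None
    for table in tables:
        dup = table.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            row = table[dup].iloc[0]
            raise ValueError(
                f"duplicate residue key {row['chain']}/{row['resnum']}{row['icode']}"
            )
        merged = table if merged is None else merged.merge(
            table, on=KEY_COLUMNS, how="outer"
        )
    if merged is None:
        raise ValueError("no score tables supplied")
    merged = merged.sort_values(["chain", "resnum", "icode"]).reset_index(drop=True)

    flag_cols = []
    for metric, cut in thresholds.items():
        if metric not in merged.columns:
            continue
        col = f"flag_{metric}"
        values = pd.to_numeric(merged[metric], errors="coerce")
        merged[col] = (values < cut).fillna(False)
        flag_cols.append(col)
    for metric in GEOMETRY_FLAG_COLUMNS:
        if metric not in merged.columns:
            continue
        col = f"flag_{metric}"
        merged[col] = merged[metric].apply(lambda v: bool(v) if pd.notna(v) else False)
        flag_cols.append(col)
    if "rama_class" in merged.columns:
        merged["flag_rama"] = (merged["rama_class"] == "outlier").fillna(False)
        flag_cols.append("flag_rama")
    merged["issue_count"] = merged[flag_cols].sum(axis=1).astype(int) if flag_cols else 0
    return merged


def _flagged_metrics(row: pd.Series) -> list[str]:
    return sorted(
        c[len("flag_"):] for c in row.index if c.startswith("flag_") and row[c]
    )


def cluster_issues(
    issues: pd.DataFrame,
    model: AtomicModel,
    cutoff: float = DEFAULT_CLUSTER_CUTOFF,
) -> list[IssueCluster]:
    """Single-linkage clusters of flagged residues at a CA-CA distance cutoff.

    Clusters are sorted by (severity desc, distinct-metric count desc,
    chain/resnum of the first member asc); ties cannot survive the
    three-key sort because member lists are disjoint and ordered.
    """
    flagged = issues[issues["issue_count"] > 0]
    if flagged.empty:
        return []
    keys, coords, counts, metric_sets = [], [], [], []
    for _, row in flagged.iterrows():
        _, res = model.get_residue(row["chain"], int(row["resnum"]), row["icode"] or "")
        ca = res.atom("CA")
        if ca is None:
            continue
        keys.append((row["chain"], int(row["resnum"]), row["icode"] or ""))
        coords.append(ca.coord)
        counts.append(int(row["issue_count"]))
        metric_sets.append(set(_flagged_metrics(row)))
    if not keys:
        return []
    coords = np.array(coords)

    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    n = len(keys)
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)

    clusters = []
    for comp in range(n_comp):
        idx = sorted(
            np.flatnonzero(labels == comp), key=lambda i: keys[i]
        )
        members = [keys[i] for i in idx]
        metrics: set[str] = set()
        for i in idx:
            metrics |= metric_sets[i]
        clusters.append(
            IssueCluster(
                members=members,
                centroid=tuple(np.mean(coords[idx], axis=0)),
                severity=int(sum(counts[i] for i in idx)),
                metrics=sorted(metrics),
            )
        )
    clusters.sort(
        key=lambda c: (-c.severity, -c.distinct_metric_count, c.members[0])
    )
    return clusters


def compare_models(
    before: tuple[GlobalFit, GeometrySummary],
    after: tuple[GlobalFit, GeometrySummary],
) -> ModelComparison:
    """dFSC = FSCavg(after) - FSCavg(before); dMolProbity likewise."""
    fit_b, geo_b = before
    fit_a, geo_a = after
    return ModelComparison(
        dfsc=fit_a.fsc_avg - fit_b.fsc_avg,
        dmolprobity=geo_a.molprobity_score - geo_b.molprobity_score,
    )


def contacts_at_site(
    model: AtomicModel,
    chain_id: str,
    resnum: int,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    insertion_code: str = "",
) -> list[Contact]:
    """Heavy-atom contacts of one residue site.

    Partner residues with any heavy-atom pair within ``cutoff`` A are
    listed once with the minimum distance; the type is ``clash`` when any
    pair has vdW overlap >= 0.4 A, else ``polar`` when the closest pair is
    N/O-N/O, else ``nonpolar``.  Sequence neighbours (i +/- 1, same chain)
    are excluded.
    """
    single = model.primary_conformer()
    site_chain, site_res = single.get_residue(chain_id, resnum, insertion_code)
    site_atoms = site_res.heavy_atoms()
    if not site_atoms:
        return []
    site_label = f"{chain_id}/{resnum}{insertion_code} {site_res.name}"
    contacts = []
    for chain in single.chains:
        for res in chain.residues:
            if chain.chain_id == chain_id and res.key == site_res.key:
                continue
            if chain.chain_id == chain_id and abs(res.number - site_res.number) <= 1:
                continue
            best = None
            clash = False
            for a in site_atoms:
                for b in res.heavy_atoms():
                    d = float(np.linalg.norm(a.coord - b.coord))
                    if d > cutoff:
                        continue
                    if vdw_radius(a.element) + vdw_radius(b.element) - d >= 0.4:
                        clash = True
                    if best is None or d < best[0]:
                        best = (d, a, b)
            if best is None:
                continue
            d, a, b = best
            if clash:
                ctype = "clash"
            elif a.element in _POLAR_ELEMENTS and b.element in _POLAR_ELEMENTS:
                ctype = "polar"
            else:
                ctype = "nonpolar"
            contacts.append(
                Contact(
                    site=site_label,
                    partner=f"{chain.chain_id}/{res.number}{res.insertion_code} {res.name}",
                    partner_chain=chain.chain_id,
                    min_distance=round(d, 3),
                    contact_type=ctype,
                )
            )
    contacts.sort(key=lambda c: c.min_distance)
    return contacts


# ---------------------------------------------------------------------------
# Report emission
# ---------------------------------------------------------------------------

REPORT_SCHEMA_VERSION = "1.0"


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, float) and np.isnan(value):
        return None
    return value


def _frame_records(df: pd.DataFrame) -> list[dict]:
    records = df.to_dict(orient="records")
    return [
        {k: _jsonable(v) if not pd.isna(v) else None for k, v in row.items()}
        for row in records
    ]


def build_report(
    out_dir,
    parameters: dict,
    global_fit: GlobalFit | None = None,
    geometry: GeometrySummary | None = None,
    issue_table: pd.DataFrame | None = None,
    clusters: list[IssueCluster] | None = None,
    timestamp: str = "",
) -> dict:
    """Write the machine- and human-readable report files.

    Emits ``report.json`` (schema-versioned; every tunable parameter
    echoed; timestamp isolated in its own field so the rest of the document
    is byte-deterministic), ``residue_scores.csv``, ``clusters.csv`` and a
    plain-text ``summary.txt`` whose first section lists clusters in rank
    order.  Files are written to a temporary location and atomically
    renamed, so failures leave no partial reports.
    """
    if global_fit is None and geometry is None and issue_table is None:
        raise ValueError("at least one score must be computed before reporting")
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": {k: _jsonable(v) for k, v in sorted(parameters.items())},
        "global_fit": asdict(global_fit) if global_fit else None,
        "geometry": asdict(geometry) if geometry else None,
        "residues": _frame_records(issue_table) if issue_table is not None else None,
        "clusters": [asdict(c) for c in clusters] if clusters is not None else None,
        "timestamp": timestamp,
    }

    files: dict[str, str] = {}
    files["report.json"] = json.dumps(report, indent=1, sort_keys=True, default=_jsonable)
    if issue_table is not None:
        files["residue_scores.csv"] = issue_table.to_csv(index=False)
    if clusters is not None:
        cluster_df = pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "severity": c.severity,
                    "n_residues": len(c.members),
                    "metrics": ";".join(c.metrics),
                    "members": ";".join(f"{ch}/{rn}{ic}" for ch, rn, ic in c.members),
                    "centroid_x": c.centroid[0],
                    "centroid_y": c.centroid[1],
                    "centroid_z": c.centroid[2],
                }
                for i, c in enumerate(clusters)
            ]
        )
        files["clusters.csv"] = cluster_df.to_csv(index=False)

    lines = ["issue clusters (ranked by severity)", "=" * 36]
    if clusters:
        for i, c in enumerate(clusters):
            lines.append(
                f"{i + 1}. severity {c.severity}, {len(c.members)} residue(s), "
                f"metrics: {', '.join(c.metrics)}; members: "
                + ", ".join(f"{ch}/{rn}{ic}" for ch, rn, ic in c.members)
            )
    else:
        lines.append("no issues flagged")
    lines += ["", "parameters", "-" * 10]
    lines += [f"{k} = {v}" for k, v in sorted(report["parameters"].items())]
    if global_fit is not None:
        lines += [
            "",
            f"FSCavg = {global_fit.fsc_avg:.4f} at {global_fit.resolution_cutoff} A",
            f"real-space CC = {global_fit.real_space_cc:.4f}",
        ]
    if geometry is not None:
        lines += [
            f"clashscore = {geometry.clashscore:.2f}",
            f"geometry composite = {geometry.molprobity_score:.2f}",
        ]
    files["summary.txt"] = "\n".join(lines) + "\n"

    for name, content in files.items():
        fd, tmp = tempfile.mkstemp(dir=out_dir, prefix=f".{name}.")
        with os.fdopen(fd, "w") as fh:
            fh.write(content)
        os.replace(tmp, os.path.join(out_dir, name))
    return report
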