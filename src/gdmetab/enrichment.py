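"""Pathway over-representation analysis against local KEGG-style annotations.

Significant metabolites (as KEGG compound IDs, e.g. ``C00031``) are tested
pathway by pathway with the one-sided Fisher exact test on the 2x2 table
(in-set & in-pathway, in-set & out, out & in-pathway, out & out), which for
a 2x2 table is exactly the hypergeometric upper tail.  P-values are
Benjamini-Hochberg adjusted across tested pathways.  Annotations are loaded
from a local TSV (pathway_id, pathway_name, then tab-joined compound IDs) —
no live database access.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .associations import adjust_bh

logger = logging.getLogger(__name__)

__all__ = ["load_annotations", "fisher_pvalue", "fisher_enrichment", "enrichment_report"]


def fisher_pvalue(k: int, K: int, n: int, N: int) -> float:
    """One-sided (enrichment) Fisher exact p for a 2x2 overlap table.

    ``P[X >= k]`` for ``X ~ Hypergeom(N, K, n)`` — the upper tail of drawing
    ``n`` compounds from a universe of ``N`` of which ``K`` are in the
    pathway and observing ``k`` or more hits.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError("inconsistent 2x2 table counts")
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Parse a pathway-annotation TSV into (pathway_id, pathway_name, members).

    Each row is ``pathway_id<TAB>pathway_name<TAB>C1<TAB>C2...``.  Rows with
    no members, duplicate member IDs within a row, or duplicate pathway IDs
    raise with the offending line number.
    """
    rows = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected pathway_id, name and >=1 member")
            pid, name, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"line {lineno}: pathway {pid!r} has no members")
            if len(set(members)) != len(members):
                raise ValueError(f"line {lineno}: duplicate member IDs in {pid!r}")
            if pid in seen:
                raise ValueError(f"line {lineno}: duplicate pathway_id {pid!r}")
            seen.add(pid)
            rows.append((pid, name, sorted(members)))
    return pd.DataFrame(rows, columns=["pathway_id", "pathway_name", "members"])


def fisher_enrichment(
    input_compounds,
    universe_compounds,
    annotations: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test per pathway with BH-FDR.

    ``k`` = |input ∩ pathway|, ``K`` = |pathway ∩ universe|, ``n`` = |input|,
    ``N`` = |universe|; ``p = P[X >= k]`` for ``X ~ Hypergeom(N, K, n)``.
    Input IDs outside the universe are dropped with a warning; pathways with
    no member in the universe are skipped.  Output sorted by ``fdr_p`` then
    pathway_id.
    """
    universe = set(universe_compounds)
    if not universe:
        raise ValueError("empty compound universe")
    inp = set(input_compounds)
    outside = inp - universe
    if outside:
        warnings.warn(
            f"{len(outside)} input compounds outside the universe were dropped",
            stacklevel=2,
        )
        inp &= universe
    if not inp:
        raise ValueError("no input compounds inside the universe")
    N, n = len(universe), len(inp)
    rows = []
    for _, row in annotations.iterrows():
        members = set(row.members) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(inp & members)
        rows.append(
            {
                "pathway_id": row.pathway_id,
                "pathway_name": row.pathway_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "fisher_p": fisher_pvalue(k, K, n, N),
            }
        )
    if not rows:
        raise ValueError("no pathway overlaps the compound universe")
    out = pd.DataFrame(rows)
    out["fdr_p"] = adjust_bh(out["fisher_p"].to_numpy())
    out["significant"] = out["fdr_p"] < alpha
    return out.sort_values(["fdr_p", "pathway_id"], kind="stable").reset_index(drop=True)


def enrichment_report(records: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Dot-plot data: the ``top_n`` pathways by ascending FDR p, with the
    -log10 FDR p and the overlap count ``k`` (dot size)."""
    top = records.sort_values(["fdr_p", "pathway_id"], kind="stable").head(top_n)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(top["fdr_p"].to_numpy())
    return pd.DataFrame(
        {
            "pathway_id": top["pathway_id"].to_numpy(),
            "pathway_name": top["pathway_name"].to_numpy(),
            "neg_log10_fdr_p": np.where(np.isfinite(neglog), neglog, 0.0),
            "count": top["k"].to_numpy(),
        }
    )
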