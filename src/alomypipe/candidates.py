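"""Homolog assignment and the NTSR candidate screen.

Candidates for non-target-site herbicide resistance are contigs whose
expression is at least 2-fold higher in the resistant pool than in the
sensitive pool at every retained time-point *including the untreated one*
(constitutive over-expression), and which belong to a gene family presumed to
drive NTSR (detoxification enzymes, transporters, stress proteins,
transcription factors). Homologs of reference genes are assigned by best
tabular alignment hit (smallest E-value) below a significance threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffexp import EPSILON, classify_profile
from .quant import ExpressionMatrix
from .simdata import Modality, NTSR_FAMILIES, TIME_POINTS

OUTFMT6_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
)


def load_hit_table(path) -> pd.DataFrame:
    """Read a 12-column tabular alignment file (outfmt-6 order)."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    _validate_hits(df)
    return df


def _validate_hits(hits: pd.DataFrame) -> None:
    for col in ("query_id", "subject_id", "e_value", "bit_score"):
        if col not in hits.columns:
            raise ValueError(f"hit table missing column {col}")
    if (pd.to_numeric(hits["e_value"], errors="coerce").isna()).any():
        bad = hits.index[pd.to_numeric(hits["e_value"], errors="coerce").isna()]
        raise ValueError(f"malformed E-values at rows {list(bad[:10])}")
    if (hits["e_value"].astype(float) < 0).any():
        raise ValueError("negative E-value")


def best_hit_homologs(
    hits: pd.DataFrame, max_evalue: float = 1e-5
) -> tuple[dict[str, str], list[str]]:
    """Per query keep the smallest-E subject (ties: highest bit score, then
    lexicographic subject id); queries whose best E-value is not < max_evalue
    are dropped. Several queries may share one subject."""
    _validate_hits(hits)
    if hits.empty:
        return {}, []
    h = hits.copy()
    h["e_value"] = h["e_value"].astype(float)
    h["bit_score"] = h["bit_score"].astype(float)
    h = h.sort_values(
        ["query_id", "e_value", "bit_score", "subject_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = h.groupby("query_id", sort=True).first()
    mapping = {
        q: str(row["subject_id"])
        for q, row in best.iterrows()
        if row["e_value"] < max_evalue
    }
    dropped = sorted(set(best.index) - set(mapping))
    return mapping, dropped


@dataclass(frozen=True)
class CandidateReport:
    """Screen output: per-contig R/S ratios and verdicts."""

    table: pd.DataFrame  # contig_id, family, ratio_<tp>.., min_ratio, verdict
    retained_time_points: tuple[str, ...]

    @property
    def candidates(self) -> pd.DataFrame:
        return self.table[self.table["verdict"] == "candidate"]

    @property
    def near_misses(self) -> pd.DataFrame:
        return self.table[self.table["verdict"] == "expression_only"]


def ntsr_candidate_filter(
    matrix: ExpressionMatrix,
    annotations: dict[str, set[str]] | dict[str, str],
    design: tuple[Modality, ...],
    qc_flags: tuple[str, ...] = (),
    fold_min: float = 2.0,
    families: tuple[str, ...] = NTSR_FAMILIES,
    eps: float = EPSILON,
) -> CandidateReport:
    """Select contigs with R/S RPKM ratio >= fold_min at every retained
    time-point including UT, affiliated to an NTSR family.

    annotations maps contig_id to family labels (a string or a set).
    Contigs meeting the expression rule but lacking an NTSR-family label are
    reported separately with verdict "expression_only".
    """
    by_name = {m.name: m for m in design}
    flagged_tp = {by_name[f].time_point for f in qc_flags if f in by_name}
    retained = tuple(
        t
        for t in TIME_POINTS
        if t not in flagged_tp
        and f"R_{t}" in matrix.rpkm.columns
        and f"S_{t}" in matrix.rpkm.columns
    )
    if "UT" not in retained:
        raise ValueError("the untreated time-point is required for the screen")
    fam_set = set(families)
    rows = []
    for cid in matrix.contigs:
        fams = annotations.get(cid, set())
        if isinstance(fams, str):
            fams = {fams}
        ntsr_fams = sorted(fams & fam_set)
        ratios = {}
        for t in retained:
            r = matrix.rpkm.at[cid, f"R_{t}"]
            s = matrix.rpkm.at[cid, f"S_{t}"]
            ratios[t] = r / s if s > 0 else r / eps
        min_ratio = min(ratios.values())
        if min_ratio >= fold_min:
            verdict = "candidate" if ntsr_fams else "expression_only"
        else:
            verdict = "rejected"
        row = {
            "contig_id": cid,
            "family": ";".join(ntsr_fams) if ntsr_fams else ";".join(sorted(fams)),
            **{f"ratio_{t}": ratios[t] for t in retained},
            "min_ratio": min_ratio,
            "verdict": verdict,
            "requires_independent_validation": verdict == "candidate",
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        order = {"candidate": 0, "expression_only": 1, "rejected": 2}
        table = table.sort_values(
            ["verdict", "min_ratio", "contig_id"],
            key=lambda s: s.map(order) if s.name == "verdict" else (-s if s.name == "min_ratio" else s),
        ).reset_index(drop=True)
    return CandidateReport(table, retained)


def known_gene_screen(
    homolog_map: dict[str, str],
    matrix: ExpressionMatrix,
    design: tuple[Modality, ...],
    qc_flags: tuple[str, ...] = (),
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Profile the homologs of previously published NTSR genes.

    Each mapped homolog's R and S time-courses are pattern-labelled; a gene is
    reported "not NTSR-associated in this dataset" unless its homolog shows
    the constitutive >= fold_min R/S ratio at every retained time-point.
    Unmapped genes are omitted (logged via the returned frame's attrs).
    """
    by_name = {m.name: m for m in design}
    flagged_tp = {by_name[f].time_point for f in qc_flags if f in by_name}
    retained = [t for t in TIME_POINTS if t not in flagged_tp]
    rows = []
    missing = []
    for gene, cid in sorted(homolog_map.items()):
        if cid not in matrix.contigs:
            missing.append(gene)
            continue
        patt = {}
        for p in ("R", "S"):
            series = {
                t: matrix.rpkm.at[cid, f"{p}_{t}"]
                for t in retained
                if f"{p}_{t}" in matrix.rpkm.columns
            }
            patt[p] = classify_profile(series)
        ratios = []
        for t in retained:
            r = matrix.rpkm.at[cid, f"R_{t}"]
            s = matrix.rpkm.at[cid, f"S_{t}"]
            ratios.append(r / s if s > 0 else r / EPSILON)
        constitutive = min(ratios) >= fold_min if ratios else False
        rows.append(
            {
                "known_gene": gene,
                "homolog_contig": cid,
                "pattern_R": patt["R"],
                "pattern_S": patt["S"],
                "ntsr_associated_here": constitutive,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["unmapped_genes"] = missing
    return df
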