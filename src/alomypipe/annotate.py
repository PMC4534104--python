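"""Peptide prediction, assembly-waste filters, and annotation tables.

Coding potential is approximated by six-frame maximal ATG-to-stop ORF
finding (floor 30 amino acids, the shortest peptide retained upstream of the
filters). The assembly-waste rule keeps contigs of at least 400 nt with RPKM
>= 1.8 in at least one modality, and peptides strictly longer than 134 amino
acids.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from ._kmers import revcomp
from .quant import ExpressionMatrix


@dataclass(frozen=True)
class PredictedPeptide:
    contig_id: str
    frame: int  # +1,+2,+3 forward; -1,-2,-3 reverse
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int  # includes the stop codon
    aa_seq: str

    def __post_init__(self):
        if (self.end - self.start + 1) % 3:
            raise ValueError("ORF span not a codon multiple")


def _orfs_in_frame(seq: str, offset: int) -> list[tuple[int, int, str]]:
    """Maximal ATG->stop ORFs in one forward frame; (start0, end0, peptide)."""
    sub = seq[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    if len(sub) < 3:
        return []
    aa = str(Seq(sub).translate())
    out = []
    region_start = 0  # codon index after the previous stop
    pos = 0
    while True:
        stop = aa.find("*", region_start)
        region_end = stop if stop != -1 else len(aa)
        m = aa.find("M", region_start, region_end)
        if m != -1 and stop != -1:
            pep = aa[m:stop]
            start0 = offset + 3 * m
            end0 = offset + 3 * (stop + 1) - 1  # include the stop codon
            out.append((start0, end0, pep))
        if stop == -1:
            break
        region_start = stop + 1
    return out


def find_orfs(contig, min_aa: int = 30) -> list[PredictedPeptide]:
    """All maximal ATG->stop ORFs of length >= min_aa in all six frames,
    longest peptide first (ties by frame then start)."""
    cid = contig.id if hasattr(contig, "id") else "contig"
    seq = (contig.sequence if hasattr(contig, "sequence") else str(contig)).upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over ACGTN")
    n = len(seq)
    peptides = []
    for offset in range(3):
        for start0, end0, pep in _orfs_in_frame(seq, offset):
            if len(pep) >= min_aa:
                peptides.append(
                    PredictedPeptide(cid, offset + 1, start0 + 1, end0 + 1, pep)
                )
    rc = revcomp(seq)
    for offset in range(3):
        for start0, end0, pep in _orfs_in_frame(rc, offset):
            if len(pep) >= min_aa:
                # map back to forward-strand coordinates
                f_start = n - end0
                f_end = n - start0
                peptides.append(
                    PredictedPeptide(cid, -(offset + 1), f_start, f_end, pep)
                )
    peptides.sort(key=lambda p: (-len(p.aa_seq), p.frame, p.start))
    return peptides


def filter_assembly(
    contigs,
    peptides: list[PredictedPeptide],
    matrix: ExpressionMatrix,
    min_len: int = 400,
    min_rpkm: float = 1.8,
    min_pep_aa: int = 134,
) -> tuple[list, list[PredictedPeptide]]:
    """Discard assembly waste.

    Contigs are retained iff length >= min_len AND max RPKM over modalities
    >= min_rpkm; peptides iff strictly longer than min_pep_aa amino acids and
    on a retained contig. Raises if a contig is missing from the matrix.
    """
    contigs = list(contigs)
    missing = [c.id for c in contigs if c.id not in matrix.contigs]
    if missing:
        raise KeyError(f"contigs absent from expression matrix: {missing[:5]}")
    max_rpkm = matrix.rpkm.max(axis=1)
    kept = [
        c for c in contigs if c.length >= min_len and max_rpkm[c.id] >= min_rpkm
    ]
    kept_ids = {c.id for c in kept}
    kept_peps = [
        p for p in peptides if len(p.aa_seq) > min_pep_aa and p.contig_id in kept_ids
    ]
    return kept, kept_peps


@dataclass
class AnnotationMap:
    """contig_id -> gene-family labels and GO term ids."""

    families: dict[str, set[str]]
    go_terms: dict[str, set[str]]

    def contigs(self) -> set[str]:
        return set(self.families) | set(self.go_terms)


def load_annotations(path, dag=None) -> AnnotationMap:
    """Read a TSV of (contig_id, source, label) rows.

    source is "family" or "go"; duplicate assignments are deduplicated; with a
    DAG given, unknown GO ids are collected into the returned map's
    `unknown_terms` attribute. Malformed rows raise with their line numbers.
    """
    families: dict[str, set[str]] = {}
    go_terms: dict[str, set[str]] = {}
    unknown = []
    bad_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["contig_id", "source"]:
                continue
            if len(parts) != 3 or not all(parts):
                bad_lines.append(lineno)
                continue
            cid, source, label = parts
            if source == "family":
                families.setdefault(cid, set()).add(label)
            elif source == "go":
                if dag is not None and label not in dag:
                    unknown.append((lineno, label))
                    continue
                go_terms.setdefault(cid, set()).add(label)
            else:
                bad_lines.append(lineno)
    if bad_lines:
        raise ValueError(f"malformed annotation rows at lines {bad_lines[:10]}")
    amap = AnnotationMap(families, go_terms)
    amap.unknown_terms = unknown
    return amap


def write_annotations(amap: AnnotationMap, path) -> None:
    rows = []
    for cid, fams in sorted(amap.families.items()):
        rows += [(cid, "family", f) for f in sorted(fams)]
    for cid, terms in sorted(amap.go_terms.items()):
        rows += [(cid, "go", t) for t in sorted(terms)]
    pd.DataFrame(rows, columns=["contig_id", "source", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_peptides_fasta(peptides: list[PredictedPeptide], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peptides):
            fh.write(
                f">{p.contig_id}_pep{i:05d} frame={p.frame:+d} "
                f"start={p.start} end={p.end}\n{p.aa_seq}\n"
            )
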