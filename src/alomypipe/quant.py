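"""Read mapping under the ungapped best-score contract, RPKM, and modality QC.

The mapping contract: ungapped placements only, at most 5 mismatches, at least
half of the read aligned, score = number of matching bases with a minimum of
24; among surviving placements only those achieving the read's global maximum
score are kept, possibly on several (redundant) contigs, and the read then
counts once towards every best-score contig.

`map_read` is the exact reference mapper (enumerates every offset of every
contig, including partial end overlaps). `BulkMapper` is the production path
for whole libraries: seed-and-extend over a 2-bit k-mer index, exact for
placements in which the read is fully embedded in the contig (guaranteed by a
pigeonhole seed layout for <=5 mismatches); end overlaps hanging more than a
few bases off a contig are not searched, which is inconsequential for reads
drawn from within transcripts.

RPKM = C * 1e9 / (N * L) with C the mapped-read count of a contig, L its
length and N the total number of reads in the library (mapped plus unmapped).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._kmers import encode, pack_points, pack_windows, revcomp


@dataclass(frozen=True)
class MappingParams:
    max_mismatches: int = 5
    min_score: int = 24
    min_aligned_frac: float = 0.5
    allow_gaps: bool = False  # fixed: the contract is ungapped

    def __post_init__(self):
        if not 0 < self.min_aligned_frac <= 1:
            raise ValueError("min_aligned_frac must be in (0, 1]")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.allow_gaps:
            raise ValueError("gapped alignment is outside the mapping contract")


class Placement(NamedTuple):
    contig_id: str
    position: int  # offset of the read's first base on the contig (may be <0)
    mismatches: int
    score: int
    strand: str = "+"


def _seq_of(contig) -> str:
    return contig if isinstance(contig, str) else contig.sequence


def _contig_items(contigs) -> list[tuple[str, str]]:
    if isinstance(contigs, dict):
        return [(k, _seq_of(v)) for k, v in contigs.items()]
    return [(c.id, c.sequence) for c in contigs]


def _placements_one(
    read_codes: np.ndarray, cid: str, ccodes: np.ndarray, params: MappingParams, strand: str
) -> list[Placement]:
    L = len(read_codes)
    n = len(ccodes)
    min_ov = math.ceil(params.min_aligned_frac * L)
    out = []
    # interior placements, vectorized over offsets
    if n >= L:
        windows = np.lib.stride_tricks.sliding_window_view(ccodes, L)
        mm = (windows != read_codes).sum(axis=1)
        score = L - mm
        ok = np.nonzero(
            (mm <= params.max_mismatches) & (score >= params.min_score)
        )[0]
        for off in ok:
            out.append(Placement(cid, int(off), int(mm[off]), int(score[off]), strand))
    # end overlaps (and the short-contig case): aligned length in [min_ov, L)
    for off in range(-(L - min_ov), n - min_ov + 1):
        sa, ea = max(0, off), min(n, off + L)
        ov = ea - sa
        if ov < min_ov or ov == L:
            continue
        mm = int((ccodes[sa:ea] != read_codes[sa - off : ea - off]).sum())
        score = ov - mm
        if mm <= params.max_mismatches and score >= params.min_score:
            out.append(Placement(cid, off, mm, score, strand))
    return out


def map_read(
    read: str,
    contigs,
    params: MappingParams = MappingParams(),
    both_strands: bool = False,
) -> list[Placement]:
    """Exact best-score mapping of one read by exhaustive offset enumeration.

    Returns every placement achieving the global maximum score (empty when the
    read is unmapped). Forward strand only unless both_strands is set.
    """
    if len(read) < 1:
        raise ValueError("empty read")
    items = _contig_items(contigs)
    all_p: list[Placement] = []
    reads = [("+", encode(read))]
    if both_strands:
        reads.append(("-", encode(revcomp(read))))
    for cid, seq in items:
        ccodes = encode(seq)
        for strand, rc in reads:
            all_p.extend(_placements_one(rc, cid, ccodes, params, strand))
    if not all_p:
        return []
    best = max(p.score for p in all_p)
    return sorted(p for p in all_p if p.score == best)


class BulkMapper:
    """Seed-and-extend mapper for whole libraries of equal-length reads.

    Contigs are concatenated with 255-sentinel gaps at least one read long, so
    a gathered window can never silently span two contigs; sentinel positions
    count as mismatches, which also admits placements overhanging a contig end
    by up to max_mismatches bases.
    """

    def __init__(
        self,
        contigs,
        read_length: int,
        params: MappingParams = MappingParams(),
        seed_k: int = 16,
    ):
        items = _contig_items(contigs)
        self.params = params
        self.read_length = read_length
        self.seed_k = seed_k
        self.names = [cid for cid, _ in items]
        self.lengths = np.array([len(seq) for _, seq in items], dtype=np.int64)
        if (self.lengths == 0).any():
            raise ValueError("zero-length contig")
        n_seeds = max(2, min(params.max_mismatches + 1, (read_length // seed_k)))
        self.seed_pos = np.unique(
            np.linspace(0, read_length - seed_k, n_seeds).astype(np.int64)
        )
        gap = read_length
        parts, starts, pos = [], [], 0
        sep = np.full(gap, 255, dtype=np.uint8)
        for _, seq in items:
            starts.append(pos)
            parts.append(encode(seq))
            parts.append(sep)
            pos += len(seq) + gap
        self.starts = np.array(starts, dtype=np.int64)
        self.codes = np.concatenate(parts) if parts else np.zeros(0, np.uint8)
        keys, valid = pack_windows(self.codes, seed_k)
        idx = np.nonzero(valid)[0]
        order = np.argsort(keys[idx], kind="stable")
        self._keys = keys[idx][order]
        self._pos = idx[order].astype(np.int64)

    def best_placements(
        self, reads: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(read index, contig index, score) of every best-score placement."""
        L = self.read_length
        p = self.params
        ri_parts, ci_parts, sc_parts = [], [], []
        chunk = 40_000
        for c0 in range(0, len(reads), chunk):
            batch = reads[c0 : c0 + chunk]
            n = len(batch)
            mat = np.frombuffer("".join(batch).encode("ascii"), dtype=np.uint8)
            if len(mat) != n * L:
                raise ValueError("BulkMapper requires equal-length reads")
            from ._kmers import _CODE

            mat = _CODE[mat].reshape(n, L)
            seeds = pack_points(mat, self.seed_pos, self.seed_k)
            cand_r, cand_g = [], []
            for j, sp in enumerate(self.seed_pos):
                keys = seeds[:, j]
                lo = np.searchsorted(self._keys, keys, side="left")
                hi = np.searchsorted(self._keys, keys, side="right")
                counts = hi - lo
                total = int(counts.sum())
                if total == 0:
                    continue
                qi = np.repeat(np.arange(n), counts)
                offsets = np.arange(total) - np.repeat(
                    np.concatenate([[0], np.cumsum(counts)[:-1]]), counts
                )
                gpos = self._pos[np.repeat(lo, counts) + offsets] - sp
                cand_r.append(qi)
                cand_g.append(gpos)
            if not cand_r:
                continue
            qi = np.concatenate(cand_r)
            gpos = np.concatenate(cand_g)
            ok = (gpos >= 0) & (gpos + L <= len(self.codes))
            qi, gpos = qi[ok], gpos[ok]
            if len(qi) == 0:
                continue
            pair = np.unique(qi * (len(self.codes) + 1) + gpos)
            qi = (pair // (len(self.codes) + 1)).astype(np.int64)
            gpos = (pair % (len(self.codes) + 1)).astype(np.int64)
            win = self.codes[gpos[:, None] + np.arange(L)]
            mm = (win != mat[qi]).sum(axis=1)
            score = L - mm
            keep = (mm <= p.max_mismatches) & (score >= p.min_score)
            qi, gpos, score = qi[keep], gpos[keep], score[keep]
            if len(qi) == 0:
                continue
            best = np.zeros(n, dtype=np.int64)
            np.maximum.at(best, qi, score)
            keep = score == best[qi]
            qi, gpos, score = qi[keep], gpos[keep], score[keep]
            ci = np.searchsorted(self.starts, gpos, side="right") - 1
            pair = np.unique(qi * len(self.names) + ci)
            uq = (pair // len(self.names)).astype(np.int64)
            uc = (pair % len(self.names)).astype(np.int64)
            ri_parts.append(uq + c0)
            ci_parts.append(uc)
            sc_parts.append(best[uq])
        if not ri_parts:
            z = np.zeros(0, dtype=np.int64)
            return z, z, z
        return (
            np.concatenate(ri_parts),
            np.concatenate(ci_parts),
            np.concatenate(sc_parts),
        )

    def count(self, reads: Sequence[str]) -> tuple[np.ndarray, int]:
        """Per-contig best-score read counts and the number of mapped reads."""
        ri, ci, _ = self.best_placements(reads)
        counts = np.zeros(len(self.names), dtype=np.int64)
        np.add.at(counts, ci, 1)
        return counts, len(np.unique(ri))


@dataclass
class ExpressionMatrix:
    """Raw counts and RPKM per contig x modality, plus sizes."""

    counts: pd.DataFrame  # index: contig ids; columns: modality names
    lengths: pd.Series  # nt per contig
    library_sizes: pd.Series  # total reads per modality
    rpkm: pd.DataFrame = field(init=False)

    def __post_init__(self):
        if (self.lengths <= 0).any():
            raise ValueError("zero-length contig in expression matrix")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        self.rpkm = (
            self.counts * 1e9 / self.library_sizes
        ).div(self.lengths, axis=0)

    @property
    def contigs(self) -> pd.Index:
        return self.counts.index

    @property
    def modalities(self) -> pd.Index:
        return self.counts.columns

    def subset(self, contig_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.counts.loc[list(contig_ids)],
            self.lengths.loc[list(contig_ids)],
            self.library_sizes,
        )

    def to_tsv(self, counts_path, rpkm_path) -> None:
        c = self.counts.copy()
        c.insert(0, "length", self.lengths)
        c.to_csv(counts_path, sep="\t", index_label="contig_id")
        self.rpkm.to_csv(rpkm_path, sep="\t", index_label="contig_id", float_format="%.6g")

    @classmethod
    def from_tsv(cls, counts_path, library_sizes: pd.Series) -> "ExpressionMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col="contig_id")
        lengths = df.pop("length")
        return cls(df, lengths, library_sizes)


def count_and_rpkm(
    reads_by_modality: dict[str, Sequence[str]],
    contigs,
    params: MappingParams = MappingParams(),
    library_sizes: dict[str, int] | None = None,
) -> ExpressionMatrix:
    """Map every library and assemble the count/RPKM matrix.

    N for RPKM is the total number of reads in each library (mapped plus
    unmapped), taken from library_sizes when given, else from the read lists.
    """
    items = _contig_items(contigs)
    names = [cid for cid, _ in items]
    lengths = pd.Series({cid: len(seq) for cid, seq in items})
    cols = {}
    sizes = {}
    mapper = None
    for mod, reads in reads_by_modality.items():
        reads = list(reads)
        if not reads:
            raise ValueError(f"empty library {mod}")
        if mapper is None:
            mapper = BulkMapper(contigs, len(reads[0]), params)
        counts, _ = mapper.count(reads)
        cols[mod] = counts
        sizes[mod] = (
            library_sizes[mod] if library_sizes is not None else len(reads)
        )
    counts_df = pd.DataFrame(cols, index=names)
    return ExpressionMatrix(counts_df, lengths, pd.Series(sizes))


def rpkm_for_coverage(
    fold_coverage: float, read_len: float, library_size: float
) -> float:
    """RPKM value corresponding to an average fold_coverage x sequencing depth.

    Independent of contig length: a contig with coverage c has
    C = c * L / read_len reads, so RPKM = c * 1e9 / (read_len * N).
    """
    if fold_coverage <= 0 or read_len <= 0 or library_size <= 0:
        raise ValueError("all arguments must be positive")
    return fold_coverage * 1e9 / (read_len * library_size)


def expressed_filter(matrix: ExpressionMatrix, threshold: float = 1.8) -> pd.Index:
    """Contigs considered expressed: max RPKM over modalities >= threshold."""
    return matrix.contigs[matrix.rpkm.max(axis=1) >= threshold]


@dataclass(frozen=True)
class QCResult:
    fractions: pd.Series  # per modality, fraction of contigs with >=1 read
    flagged: tuple[str, ...]
    skipped: bool = False


def modality_qc(matrix: ExpressionMatrix, alpha: float = 0.05) -> QCResult:
    """Flag modalities whose fraction of detected contigs is a significant low
    outlier (two-sided Grubbs at alpha, flagged only when below the mean)."""
    from .diffexp import grubbs_outlier

    fractions = (matrix.counts > 0).mean(axis=0)
    if len(fractions) < 3:
        warnings.warn("fewer than 3 modalities; detection-fraction QC skipped")
        return QCResult(fractions, (), skipped=True)
    res = grubbs_outlier(fractions.to_numpy(), alpha=alpha)
    flagged: tuple[str, ...] = ()
    if res.is_outlier and fractions.iloc[res.index] < fractions.mean():
        flagged = (str(fractions.index[res.index]),)
    return QCResult(fractions, flagged)
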