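"""Draft contig assembly and iterative redundancy reduction.

The draft stage is a minimal de Bruijn assembler standing in for the external
base assembler: k-mers occurring once are pruned as sequencing errors, contigs
are the maximal non-branching paths of the remaining graph, and simple bubbles
whose arms diverge by at most `max_divergence` are collapsed onto the
higher-coverage arm. Reads are treated as stranded, so the graph is built on
the forward strand only.

The reduction stage implements the iterative scheme that is the point of the
procedure: per iteration, containment clustering absorbs short redundant
contigs into longer ones (within an overhang allowance, at an identity
threshold), then a greedy merger joins contigs with long terminal overlaps.
Iterations run from the most to the least stringent identity (99% down to
92%), each iteration constraining the next; the final, most permissive
iteration collapses haplotype (allelic) contig pairs.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._kmers import SeqIndex, encode, revcomp, shared_kmer_offsets

DEFAULT_SCHEDULE = ((99.0, 20, 100), (97.0, 20, 100), (95.0, 20, 75), (92.0, 20, 75))


@dataclass
class Contig:
    """An assembled sequence plus the ids of everything absorbed into it."""

    id: str
    sequence: str
    members: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.members:
            self.members = (self.id,)
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"contig {self.id} contains non-ACGTN characters")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DraftParams:
    """De Bruijn draft parameters: ascending odd k schedule, bubble tolerance."""

    kmer_schedule: tuple[int, ...] = tuple(range(41, 86, 4))
    max_divergence: float = 0.01

    def __post_init__(self):
        for k in self.kmer_schedule:
            if k % 2 == 0:
                raise ValueError("k-mer sizes must be odd")


@dataclass(frozen=True)
class ReductionSchedule:
    """Ordered (identity %, overhang nt, HSP length nt) triples, stringency
    non-increasing across iterations."""

    iterations: tuple[tuple[float, int, int], ...] = DEFAULT_SCHEDULE

    def __post_init__(self):
        last = None
        for ident, overhang, hsp in self.iterations:
            if not 92.0 <= ident <= 99.0:
                raise ValueError("identity percentage must be within [92, 99]")
            if overhang < 0 or hsp <= 0:
                raise ValueError("invalid overhang/HSP length")
            if last is not None and ident > last:
                raise ValueError("identity must be non-increasing across iterations")
            last = ident


# ---------------------------------------------------------------------------
# Draft assembly


def _count_kmers(reads, k, weights=None) -> Counter:
    counts: Counter = Counter()
    if weights is None:
        for s in reads:
            if len(s) >= k:
                counts.update(s[i : i + k] for i in range(len(s) - k + 1))
    else:
        for s, w in zip(reads, weights):
            if len(s) < k:
                continue
            for _ in range(int(w)):
                counts.update(s[i : i + k] for i in range(len(s) - k + 1))
    return counts


def _unitigs(kmers: set[str], counts) -> list[tuple[str, float]]:
    """Maximal non-branching paths; returns (sequence, mean k-mer coverage)."""
    succ: dict[str, list[str]] = {}
    pred: dict[str, list[str]] = {}
    for km in kmers:
        succ.setdefault(km[:-1], []).append(km[-1])
        pred.setdefault(km[1:], []).append(km[0])

    def internal(node: str) -> bool:
        return len(succ.get(node, ())) == 1 and len(pred.get(node, ())) == 1

    visited: set[str] = set()
    out: list[tuple[str, float]] = []

    def walk(start_kmer: str) -> None:
        u = start_kmer[:-1]
        bases = [start_kmer[-1]]
        cov = [counts[start_kmer]]
        cur = start_kmer
        visited.add(cur)
        while True:
            v = cur[1:]
            if not internal(v):
                break
            nxt = v + succ[v][0]
            if nxt in visited:
                break
            visited.add(nxt)
            bases.append(nxt[-1])
            cov.append(counts[nxt])
            cur = nxt
        out.append((u + "".join(bases), float(np.mean(cov))))

    for km in sorted(kmers):
        if km in visited:
            continue
        if not internal(km[:-1]):
            walk(km)
    # anything left lies on cycles: break each at its smallest k-mer
    for km in sorted(kmers):
        if km not in visited:
            walk(km)
    return out


def _pop_bubbles(
    unitigs: list[tuple[str, float]], k: int, max_divergence: float
) -> list[tuple[str, float]]:
    """Drop the lower-coverage arm of simple substitution bubbles.

    Two unitigs form a bubble when they share their first and last (k-1)-mers
    and have equal length; they are collapsed when their divergence (mismatch
    fraction) is at most max_divergence.
    """
    groups: dict[tuple[str, str, int], list[int]] = {}
    for i, (seq, _) in enumerate(unitigs):
        groups.setdefault((seq[: k - 1], seq[-(k - 1) :], len(seq)), []).append(i)
    dead: set[int] = set()
    for idx in groups.values():
        if len(idx) < 2:
            continue
        # keep higher coverage (tie: lexicographically smaller sequence)
        idx = sorted(idx, key=lambda i: (-unitigs[i][1], unitigs[i][0]))
        keeper = idx[0]
        ka = encode(unitigs[keeper][0])
        for other in idx[1:]:
            oa = encode(unitigs[other][0])
            if (ka != oa).sum() / len(ka) <= max_divergence:
                dead.add(other)
    return [u for i, u in enumerate(unitigs) if i not in dead]


def _extend_tips(seq: str, counts, kept: set[str], k: int, max_ext: int) -> str:
    """Extend a unitig's ends through unambiguous singleton k-mers.

    Terminal k-mers of a transcript are covered by a single read start and
    would otherwise be lost to the count-1 pruning; an extension is taken only
    when exactly one continuation exists in the unpruned graph and it is not
    already part of the pruned graph, so error branches (which compete with a
    kept continuation) never qualify.
    """
    for _ in range(max_ext):
        node = seq[-(k - 1) :]
        cand = [b for b in "ACGT" if node + b in counts]
        if len(cand) != 1 or (node + cand[0]) in kept:
            break
        seq = seq + cand[0]
    for _ in range(max_ext):
        node = seq[: k - 1]
        cand = [b for b in "ACGT" if b + node in counts]
        if len(cand) != 1 or (cand[0] + node) in kept:
            break
        seq = cand[0] + seq
    return seq


def draft_assemble(
    reads,
    k: int,
    *,
    min_count: int = 2,
    max_divergence: float = 0.01,
    pseudo_reads=(),
    pseudo_weight: int = 2,
    id_prefix: str | None = None,
) -> list[Contig]:
    """One de Bruijn pass: count, prune singletons, walk unitigs, pop bubbles,
    extend tips through unambiguous singleton k-mers.

    pseudo_reads (carry-over contigs from a previous iteration) are counted
    with multiplicity pseudo_weight so they survive the singleton pruning.
    """
    reads = list(reads)
    if reads and k >= min(len(r) for r in reads) + 1:
        # contigs must span at least one k-mer of some read
        pass
    counts = _count_kmers(reads, k)
    if pseudo_reads:
        counts.update(_count_kmers(pseudo_reads, k, weights=[pseudo_weight] * len(pseudo_reads)))
    kept = {km for km, c in counts.items() if c >= min_count}
    if not kept:
        return []
    unitigs = _unitigs(kept, counts)
    popped = _pop_bubbles(unitigs, k, max_divergence)
    if len(popped) < len(unitigs):
        # re-walk: popping a bubble re-joins the through-path
        kept = set()
        for seq, _ in popped:
            kept.update(seq[i : i + k] for i in range(len(seq) - k + 1))
        unitigs = _unitigs(kept, counts)
    unitigs = [
        (_extend_tips(seq, counts, kept, k, max_ext=k - 1), cov)
        for seq, cov in unitigs
    ]
    unitigs.sort(key=lambda u: (-len(u[0]), u[0]))
    prefix = id_prefix if id_prefix is not None else f"k{k}"
    width = max(4, len(str(len(unitigs))))
    return [Contig(f"{prefix}_{i:0{width}d}", seq) for i, (seq, _) in enumerate(unitigs)]


def _tile(seq: str, k: int) -> list[str]:
    """Tile a contig into 2k-long fragments stepping k (covers every k-mer)."""
    if len(seq) <= 2 * k:
        return [seq]
    frags = []
    for start in range(0, len(seq) - k, k):
        frags.append(seq[start : start + 2 * k])
    return frags


def iterative_draft(reads, params: DraftParams = DraftParams()) -> list[Contig]:
    """Run the draft assembler over the ascending k schedule.

    Contigs of the previous iteration are re-injected as tiled pseudo-reads
    (counted with weight 2) so that regions assembled at a small k persist into
    the large-k graphs even where read coverage alone is too thin. The output
    is the final iteration's contig set, deduplicated exactly.
    """
    reads = list(reads)
    contigs: list[Contig] = []
    for k in params.kmer_schedule:
        pseudo = [f for c in contigs for f in _tile(c.sequence, k)]
        contigs = draft_assemble(
            reads,
            k,
            max_divergence=params.max_divergence,
            pseudo_reads=pseudo,
        )
    seen: set[str] = set()
    out = []
    for c in contigs:
        if c.sequence not in seen:
            seen.add(c.sequence)
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Containment clustering and overlap merging

_SEED_K = 15
_BRUTE_LEN = 30  # below this, candidate offsets are enumerated exhaustively


def _identity_at(
    acodes: np.ndarray, bcodes: np.ndarray, off: int
) -> tuple[int, int]:
    """(matches, aligned columns) of an ungapped placement of B at offset off."""
    sa = max(0, off)
    ea = min(len(acodes), off + len(bcodes))
    if ea <= sa:
        return 0, 0
    a = acodes[sa:ea]
    b = bcodes[sa - off : ea - off]
    return int((a == b).sum()), ea - sa


def _candidate_offsets(index: SeqIndex, query: str, step: int) -> dict[int, set[int]]:
    """target index -> candidate diagonal offsets, from shared seed k-mers."""
    si, offs, _ = shared_kmer_offsets(index, query, step=step)
    cands: dict[int, set[int]] = {}
    for s, o in zip(si.tolist(), offs.tolist()):
        cands.setdefault(s, set()).add(o)
    return cands


def containment_cluster(
    contigs, identity_pct: float, overhang_nt: int, check_rc: bool = True
) -> list[Contig]:
    """Absorb each contig that aligns (ungapped, either strand) into a longer
    contig covering all but at most overhang_nt of it at >= identity_pct.

    Hosts are considered longest-first (ties by id); absorption records the
    absorbed contig's member closure on the host. The output is closed: no
    remaining contig is absorbable into another at the same stringency.
    """
    if not 0 < identity_pct <= 100:
        raise ValueError("identity_pct must be in (0, 100]")
    if overhang_nt < 0:
        raise ValueError("overhang_nt must be >= 0")
    contigs = list(contigs)
    order = sorted(range(len(contigs)), key=lambda i: (contigs[i].length, contigs[i].id))
    by_id = {c.id: i for i, c in enumerate(contigs)}
    codes = [encode(c.sequence) for c in contigs]
    members = [list(c.members) for c in contigs]
    dead = [False] * len(contigs)
    seqs = {c.id: c.sequence for c in contigs}
    index = SeqIndex(seqs, k=_SEED_K) if contigs else None
    name_to_i = {name: by_id[name] for name in (index.names if index else [])}

    def host_priority(i: int):
        return (-contigs[i].length, contigs[i].id)

    for bi in order:
        if dead[bi]:
            continue
        B = contigs[bi]
        variants = [(B.sequence, codes[bi])]
        if check_rc:
            rc = revcomp(B.sequence)
            variants.append((rc, encode(rc)))
        # gather candidate (host, offset, strand) triples
        cand: dict[int, list[tuple[int, int]]] = {}

        def add(ai: int, off: int, strand: int):
            if ai == bi or dead[ai]:
                return
            A = contigs[ai]
            if (A.length, A.id) <= (B.length, B.id):
                return  # only absorb into strictly "larger" contigs
            cand.setdefault(ai, []).append((off, strand))

        if B.length < _BRUTE_LEN or index is None:
            for ai, A in enumerate(contigs):
                if dead[ai] or ai == bi:
                    continue
                for off in range(-overhang_nt, A.length - B.length + overhang_nt + 1):
                    add(ai, off, 0)
                    if check_rc:
                        add(ai, off, 1)
        else:
            step = max(1, (B.length - _SEED_K) // 40)
            for strand, (seq, _) in enumerate(variants):
                for name_i, offs in _candidate_offsets(index, seq, step).items():
                    ai = name_to_i[index.names[name_i]]
                    for off in offs:
                        add(ai, off, strand)

        for ai in sorted(cand, key=host_priority):
            done = False
            for off, strand in sorted(set(cand[ai])):
                bc = variants[strand][1]
                matches, cols = _identity_at(codes[ai], bc, off)
                if cols >= B.length - overhang_nt and cols > 0:
                    if matches / cols * 100.0 >= identity_pct - 1e-9:
                        members[ai].extend(members[bi])
                        dead[bi] = True
                        done = True
                        break
            if done:
                break

    out = []
    for i, c in enumerate(contigs):
        if not dead[i]:
            out.append(Contig(c.id, c.sequence, tuple(members[i])))
    return out


def _terminal_overlaps(contigs, codes, alive, identity_pct, hsp_len):
    """All admissible terminal-overlap merges among alive contigs.

    Returns tuples (overlap_len, a_index, b_index, offset, strand) where B
    (possibly reverse-complemented, strand=1) extends A to the right when
    placed at `offset` on A.
    """
    seqs = {contigs[i].id: contigs[i].sequence for i in range(len(contigs)) if alive[i]}
    if len(seqs) < 2:
        return []
    index = SeqIndex(seqs, k=_SEED_K)
    name_to_i = {c.id: i for i, c in enumerate(contigs)}
    found = []
    small = [i for i in range(len(contigs)) if alive[i] and contigs[i].length < _BRUTE_LEN]
    for bi in range(len(contigs)):
        if not alive[bi]:
            continue
        B = contigs[bi]
        variants = [(B.sequence, codes[bi])]
        rcseq = revcomp(B.sequence)
        variants.append((rcseq, encode(rcseq)))
        cand: dict[tuple[int, int], set[int]] = {}
        if B.length < _BRUTE_LEN:
            for ai in range(len(contigs)):
                if not alive[ai] or ai == bi:
                    continue
                for strand in (0, 1):
                    for off in range(1, contigs[ai].length):
                        cand.setdefault((ai, strand), set()).add(off)
        else:
            step = max(1, (B.length - _SEED_K) // 40)
            for strand, (seq, _) in enumerate(variants):
                for name_i, offs in _candidate_offsets(index, seq, step).items():
                    ai = name_to_i[index.names[name_i]]
                    if ai != bi and alive[ai]:
                        cand.setdefault((ai, strand), set()).update(offs)
            # a long B may also extend a short A enumerated exhaustively above
            for ai in small:
                if ai != bi:
                    for strand in (0, 1):
                        cand.setdefault((ai, strand), set()).update(
                            range(1, contigs[ai].length)
                        )
        for (ai, strand), offs in cand.items():
            A = contigs[ai]
            bc = variants[strand][1]
            for off in sorted(offs):
                if off <= 0 or off + len(bc) <= A.length:
                    continue  # not a right-extension
                ov = A.length - off
                if ov < hsp_len:
                    continue
                matches, cols = _identity_at(codes[ai], bc, off)
                if cols == ov and matches / cols * 100.0 >= identity_pct - 1e-9:
                    found.append((ov, ai, bi, off, strand))
    return found


def overlap_merge(contigs, identity_pct: float, hsp_len_nt: int) -> list[Contig]:
    """Greedily merge contigs sharing a terminal ungapped overlap of at least
    hsp_len_nt at >= identity_pct, longest overlaps first.

    At mismatching overlap columns the consensus takes the base of the longer
    input contig (ties: lexicographically smaller base).
    """
    if hsp_len_nt <= 0:
        raise ValueError("hsp_len_nt must be positive")
    contigs = [Contig(c.id, c.sequence, tuple(c.members)) for c in contigs]
    codes = [encode(c.sequence) for c in contigs]
    alive = [True] * len(contigs)
    while True:
        cands = _terminal_overlaps(contigs, codes, alive, identity_pct, hsp_len_nt)
        if not cands:
            break
        cands.sort(key=lambda t: (-t[0], contigs[t[1]].id, contigs[t[2]].id, t[4]))
        merged_any = False
        touched: set[int] = set()
        for ov, ai, bi, off, strand in cands:
            if not (alive[ai] and alive[bi]) or ai in touched or bi in touched:
                continue
            A, B = contigs[ai], contigs[bi]
            bseq = B.sequence if strand == 0 else revcomp(B.sequence)
            bcod = codes[bi] if strand == 0 else encode(bseq)
            # consensus over the overlap region
            a_ov = codes[ai][off:]
            b_ov = bcod[:ov]
            if A.length > B.length:
                cons = a_ov.copy()
            elif B.length > A.length:
                cons = b_ov.copy()
            else:
                cons = np.minimum(a_ov, b_ov)
            seq = A.sequence[:off] + _decode(cons) + bseq[ov:]
            if A.length > B.length or (A.length == B.length and A.id <= B.id):
                new_id = A.id
            else:
                new_id = B.id
            new = Contig(new_id, seq, tuple(A.members) + tuple(B.members))
            alive[ai] = alive[bi] = False
            touched.update((ai, bi))
            contigs.append(new)
            codes.append(encode(seq))
            alive.append(True)
            merged_any = True
        if not merged_any:
            break
    return [c for i, c in enumerate(contigs) if alive[i]]


def _decode(codes: np.ndarray) -> str:
    from ._kmers import decode as _d

    return _d(codes)


def iterative_reduce(
    contigs, schedule: ReductionSchedule = ReductionSchedule()
) -> list[Contig]:
    """Apply containment clustering then overlap merging per schedule iteration,
    repeating within each iteration until a fixed point, from the most to the
    least stringent identity."""
    current = list(contigs)
    for ident, overhang, hsp in schedule.iterations:
        while True:
            n_before = len(current)
            current = containment_cluster(current, ident, overhang)
            current = overlap_merge(current, ident, hsp)
            if len(current) == n_before:
                # one more containment check for closure after merging
                closed = containment_cluster(current, ident, overhang)
                if len(closed) == len(current):
                    current = closed
                    break
                current = closed
    current.sort(key=lambda c: (-c.length, c.id))
    return current


def assemble(
    reads,
    draft_params: DraftParams = DraftParams(),
    schedule: ReductionSchedule = ReductionSchedule(),
) -> list[Contig]:
    """Full assembly: iterative draft then iterative redundancy reduction."""
    return iterative_reduce(iterative_draft(reads, draft_params), schedule)


def write_fasta(contigs, path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n{c.sequence}\n")


def write_membership(contigs, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tmember_id\n")
        for c in contigs:
            for m in c.members:
                fh.write(f"{c.id}\t{m}\n")


def read_fasta(path) -> list[Contig]:
    from Bio import SeqIO

    return [Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
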