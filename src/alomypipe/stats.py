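"""Assembly summary and comparative-genomics arithmetic.

N50, gene density and genome coverage (at the printed rounding conventions),
core-gene completeness, Pfam-family rank correlation and cross-resource
family-sharing patterns.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class AssemblySummary:
    n_contigs: int
    total_size: int
    mean_length: float
    n50: int


def n50(lengths) -> int:
    """Smallest length L such that contigs >= L sum to at least half the total."""
    ls = sorted(int(x) for x in lengths)
    if not ls:
        raise ValueError("empty length list")
    if any(x <= 0 for x in ls):
        raise ValueError("lengths must be positive")
    ls.reverse()
    half = sum(ls) / 2
    acc = 0
    for x in ls:
        acc += x
        if acc >= half:
            return x
    return ls[-1]


def assembly_summary(lengths) -> AssemblySummary:
    ls = [int(x) for x in lengths]
    return AssemblySummary(
        n_contigs=len(ls),
        total_size=sum(ls),
        mean_length=float(np.mean(ls)),
        n50=n50(ls),
    )


def gene_density(n_genes: float, genome_mb: float) -> int:
    """Protein-coding genes per Mb of genome, rounded to an integer."""
    if genome_mb <= 0:
        raise ValueError("genome size must be positive")
    return int(round(n_genes / genome_mb))


def genome_coverage(assembly_mb: float, genome_mb: float) -> float:
    """Assembly as percent of genome, one decimal."""
    if assembly_mb <= 0 or genome_mb <= 0:
        raise ValueError("sizes must be positive")
    return round(100.0 * assembly_mb / genome_mb, 1)


def completeness(
    core_matches, n_core: int = 248, min_frac: float = 0.70
) -> tuple[int, float]:
    """Count core proteins recovered as 'complete' (best aligned fraction
    strictly greater than min_frac) and the percentage of the core set."""
    best: dict[str, float] = {}
    for core_id, frac in core_matches:
        if not 0 <= frac <= 1:
            raise ValueError("aligned fraction outside [0, 1]")
        if frac > best.get(core_id, -1.0):
            best[core_id] = frac
    complete = sum(1 for f in best.values() if f > min_frac)
    return complete, round(100.0 * complete / n_core, 1)


def family_rank_correlation(counts_a: dict, counts_b: dict) -> float:
    """Pearson correlation of the family-count rank vectors over the union of
    families (absent families count 0; ties get average ranks)."""
    fams = sorted(set(counts_a) | set(counts_b))
    if len(fams) < 3:
        raise ValueError("need at least 3 families")
    a = np.array([counts_a.get(f, 0) for f in fams], dtype=float)
    b = np.array([counts_b.get(f, 0) for f in fams], dtype=float)
    ra, rb = rankdata(a), rankdata(b)
    if ra.std() == 0 or rb.std() == 0:
        warnings.warn("constant ranks; correlation undefined")
        return float("nan")
    return float(np.corrcoef(ra, rb)[0, 1])


def family_sharing(memberships: dict[str, set]) -> dict:
    """Presence-pattern counts over the union of families.

    Returns {"patterns": {tuple(resources): count}, "present_in_all": int,
    "specific": {resource: count}}; pattern counts sum to the union size.
    """
    if len(memberships) < 2:
        raise ValueError("need at least 2 resources")
    resources = sorted(memberships)
    union = set().union(*memberships.values())
    patterns: dict[tuple, int] = {}
    for fam in union:
        patt = tuple(r for r in resources if fam in memberships[r])
        patterns[patt] = patterns.get(patt, 0) + 1
    return {
        "patterns": patterns,
        "present_in_all": patterns.get(tuple(resources), 0),
        "specific": {r: patterns.get((r,), 0) for r in resources},
    }
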