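"""Synthetic pooled time-course RNA-seq data for herbicide-response screening.

Emulates the study design the downstream pipeline expects: two phenotype pools
(R, herbicide-resistant; S, sensitive), seven time-points (untreated plus 6, 12,
24, 36, 48 and 73 hours after treatment), one pooled single-end 100-base
library per phenotype x time-point (14 libraries). Transcripts are diploid:
each unigene carries two haplotype sequences differing by substitutions at a
configurable heterozygosity rate. Expression truth is planted per effect class
(common herbicide response, phenotype-specific response, constitutively
R-over-expressed NTSR candidates, decoys), so every downstream stage can be
scored against a known answer.

Pooling is emulated at the truth level: each library's per-transcript weight is
the mean of `pool_size` lognormal individual-plant multipliers, mirroring
equimolar pooling of individual RNA samples.
"""
from __future__ import annotations

import dataclasses
import os
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmers import BASES, decode

PHENOTYPES = ("R", "S")
TIME_POINTS = ("UT", "6HAT", "12HAT", "24HAT", "36HAT", "48HAT", "73HAT")
TREATED_TIME_POINTS = TIME_POINTS[1:]

#: Controlled vocabulary of gene families presumed to drive non-target-site
#: resistance (detoxification / compensation families).
NTSR_FAMILIES = (
    "cytochrome_P450",
    "glycosyltransferase",
    "glutathione_S_transferase",
    "ABC_transporter",
    "peroxidase",
    "esterase",
    "disease_resistance",
    "transcription_factor",
)

#: Background families with no expected link to resistance.
OTHER_FAMILIES = (
    "protein_kinase",
    "ribosomal_protein",
    "photosystem_subunit",
    "histone",
    "aquaporin",
)


@dataclass(frozen=True)
class Modality:
    """One pooled sequencing library: a phenotype at a time-point."""

    name: str
    phenotype: str
    time_point: str
    library_size: int


def modality_name(phenotype: str, time_point: str) -> str:
    return f"{phenotype}_{time_point}"


def default_design(library_size: int = 200_000) -> tuple[Modality, ...]:
    """The 14-library design: 2 phenotypes x 7 time-points."""
    return tuple(
        Modality(modality_name(p, t), p, t, library_size)
        for p in PHENOTYPES
        for t in TIME_POINTS
    )


def _profile(
    r_ut: float = 1.0,
    r_treated: float = 1.0,
    s_ut: float = 1.0,
    s_treated: float = 1.0,
) -> dict[str, float]:
    prof = {}
    for t in TIME_POINTS:
        prof[modality_name("R", t)] = r_ut if t == "UT" else r_treated
        prof[modality_name("S", t)] = s_ut if t == "UT" else s_treated
    return prof


@dataclass(frozen=True)
class EffectClass:
    """A planted expression-truth class.

    fold maps modality name -> multiplicative factor on base expression
    (missing modalities default to 1). family_pool, when set, draws each
    transcript's gene-family label from that pool.
    """

    name: str
    n: int
    fold: dict[str, float] = field(default_factory=dict)
    family_pool: tuple[str, ...] | None = None
    base_scale: float = 1.0


def default_effect_classes(n_transcripts: int, fold: float = 4.0) -> tuple[EffectClass, ...]:
    """Planted structure used throughout: fractions of the transcriptome per class.

    The herbicide-response classes use a `fold`-times effect (default 4x, i.e.
    comfortably past the 2-fold call threshold); NTSR candidates are
    constitutively `fold`-times higher in R than in S at every time-point
    including UT; the UT decoy matches candidates everywhere except UT and must
    be rejected by the candidate filter. The abundant_down class emulates
    highly expressed photosynthesis-type transcripts shut down by the
    herbicide; its mass, together with the class fractions below, balances the
    total transcript output of treated and untreated libraries, so that
    proportional read sampling does not impose a spurious global fold-change
    on unregulated transcripts.
    """
    frac = lambda f: max(1, round(n_transcripts * f))
    down = 1.0 / fold
    return (
        EffectClass("common_up", frac(0.06), _profile(r_treated=fold, s_treated=fold)),
        EffectClass("common_down", frac(0.06), _profile(r_treated=down, s_treated=down)),
        EffectClass(
            "abundant_down",
            frac(0.04),
            _profile(r_treated=0.1, s_treated=0.1),
            base_scale=8.0,
        ),
        EffectClass("S_specific_up", frac(0.05), _profile(s_treated=fold)),
        EffectClass("R_specific_down", frac(0.05), _profile(r_treated=down)),
        EffectClass("R_specific_up", frac(1 / 30), _profile(r_treated=fold)),
        EffectClass(
            "ntsr_candidate",
            frac(0.05),
            _profile(r_ut=fold, r_treated=fold),
            family_pool=NTSR_FAMILIES,
        ),
        EffectClass(
            "ut_decoy",
            frac(0.03),
            _profile(r_treated=fold),
            family_pool=NTSR_FAMILIES,
        ),
        EffectClass(
            "ntsr_no_family",
            frac(0.02),
            _profile(r_ut=fold, r_treated=fold),
            family_pool=OTHER_FAMILIES,
        ),
        EffectClass("low_expression", frac(0.05), {}, base_scale=1e-3),
    )


@dataclass(frozen=True)
class SimConfig:
    """Simulator configuration; defaults give the full-size pooled design."""

    n_transcripts: int = 2000
    length_range: tuple[int, int] = (600, 1400)
    het_rate: float = 0.005
    read_length: int = 100
    error_rate: float = 0.003
    library_size: int = 200_000
    seed: int = 0
    effect_classes: tuple[EffectClass, ...] | None = None
    pool_size: int = 6
    pool_sigma: float = 0.25
    abundance_sigma: float = 0.25
    dropout: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if not 0 <= self.het_rate < 0.1:
            raise ValueError("het_rate must be in [0, 0.1)")
        if self.length_range[0] < self.read_length:
            raise ValueError("minimum transcript length shorter than read length")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        classes = self.classes
        if sum(c.n for c in classes) > self.n_transcripts:
            raise ValueError("effect-class sizes exceed n_transcripts")

    @property
    def classes(self) -> tuple[EffectClass, ...]:
        if self.effect_classes is not None:
            return self.effect_classes
        return default_effect_classes(self.n_transcripts)

    def design(self) -> tuple[Modality, ...]:
        return default_design(self.library_size)


@dataclass
class TranscriptTruth:
    """A simulated unigene with two haplotypes and planted expression truth."""

    id: str
    hapA_seq: str
    hapB_seq: str
    base_expression: float
    cls: str
    family: str | None
    fold: dict[str, float]
    weight: dict[str, float]

    @property
    def length(self) -> int:
        return len(self.hapA_seq)


def _rng(config: SimConfig, *streams) -> np.random.Generator:
    parts = [config.seed & 0x7FFFFFFF]
    for s in streams:
        if isinstance(s, str):
            parts.append(zlib.crc32(s.encode()) & 0x7FFFFFFF)
        else:
            parts.append(int(s) & 0x7FFFFFFF)
    return np.random.default_rng(parts)


def generate_transcripts(config: SimConfig) -> list[TranscriptTruth]:
    """Deterministically generate the diploid transcript truth set."""
    rng = _rng(config, "transcripts")
    n = config.n_transcripts
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    design = config.design()
    mod_names = [m.name for m in design]

    # class label per transcript: planted classes first, remainder stable
    labels: list[tuple[str, EffectClass | None]] = []
    for cls in config.classes:
        labels += [(cls.name, cls)] * cls.n
    labels += [("stable", None)] * (n - len(labels))

    pool_noise = rng.lognormal(
        0.0, config.pool_sigma, size=(n, len(design), config.pool_size)
    ).mean(axis=2) if config.pool_sigma > 0 else np.ones((n, len(design)))

    transcripts = []
    width = max(4, len(str(n)))
    for i in range(n):
        L = int(lengths[i])
        codesA = rng.integers(0, 4, size=L, dtype=np.uint8)
        het = rng.random(L) < config.het_rate
        codesB = codesA.copy()
        if het.any():
            shift = rng.integers(1, 4, size=int(het.sum()), dtype=np.uint8)
            codesB[het] = (codesA[het] + shift) % 4
        name, cls = labels[i]
        base = float(rng.lognormal(0.0, config.abundance_sigma))
        if cls is not None:
            base *= cls.base_scale
        fold = {m: (cls.fold.get(m, 1.0) if cls else 1.0) for m in mod_names}
        if cls is not None and cls.family_pool:
            family = str(rng.choice(cls.family_pool))
        elif rng.random() < 0.2:
            family = str(rng.choice(NTSR_FAMILIES + OTHER_FAMILIES))
        else:
            family = None
        weight = {
            m: base * fold[m] * float(pool_noise[i, j])
            for j, m in enumerate(mod_names)
        }
        transcripts.append(
            TranscriptTruth(
                id=f"t{i:0{width}d}",
                hapA_seq=decode(codesA),
                hapB_seq=decode(codesB),
                base_expression=base,
                cls=name,
                family=family,
                fold=fold,
                weight=weight,
            )
        )
    return transcripts


@dataclass
class ReadSet:
    """Simulated reads for one modality plus their per-read truth origins."""

    modality: Modality
    ids: list[str]
    seqs: list[str]
    truth: pd.DataFrame  # read_id, transcript_id, haplotype, start

    def __len__(self) -> int:
        return len(self.seqs)

    def write_fastq(self, path: str | os.PathLike) -> None:
        qual = "I" * (len(self.seqs[0]) if self.seqs else 0)
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.seqs):
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    def write_truth(self, path: str | os.PathLike) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def library_weights(
    transcripts: list[TranscriptTruth], modality: Modality, config: SimConfig
) -> np.ndarray:
    """Raw sampling weights for one library (before dropout)."""
    w = np.array([t.weight[modality.name] for t in transcripts])
    short = np.array([t.length < config.read_length for t in transcripts])
    if short.any():
        warnings.warn(
            f"{int(short.sum())} transcripts shorter than the read length were "
            f"skipped in {modality.name}"
        )
        w[short] = 0.0
    return w


def simulate_library(
    transcripts: list[TranscriptTruth], modality: Modality, config: SimConfig
) -> ReadSet:
    """Draw one pooled library of single-end reads with substitution errors."""
    rng = _rng(config, "library", modality.name)
    n_t = len(transcripts)
    w = library_weights(transcripts, modality, config)
    frac = config.dropout.get(modality.name, 0.0)
    if frac > 0:
        k = int(round(frac * n_t))
        drop = rng.choice(n_t, size=k, replace=False)
        w = w.copy()
        w[drop] = 0.0
    if w.sum() <= 0:
        raise ValueError(f"no expressible transcripts in {modality.name}")
    p = w / w.sum()
    N = modality.library_size
    R = config.read_length

    idx = rng.choice(n_t, size=N, p=p)
    hap = rng.integers(0, 2, size=N)
    lengths = np.array([t.length for t in transcripts])
    starts = (rng.random(N) * (lengths[idx] - R + 1)).astype(np.int64)

    hapcodes = [
        (
            np.frombuffer(t.hapA_seq.encode(), dtype=np.uint8),
            np.frombuffer(t.hapB_seq.encode(), dtype=np.uint8),
        )
        for t in transcripts
    ]
    err = rng.random((N, R)) < config.error_rate
    n_err = int(err.sum())
    shifts = rng.integers(1, 4, size=n_err, dtype=np.uint8)

    code_of = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(BASES):
        code_of[ord(b)] = i
    base_of = np.frombuffer(BASES.encode(), dtype=np.uint8)

    seqs: list[str] = []
    e0 = 0
    err_rows = err.any(axis=1)
    for r in range(N):
        arr = hapcodes[idx[r]][hap[r]][starts[r] : starts[r] + R]
        if err_rows[r]:
            arr = arr.copy()
            cols = np.nonzero(err[r])[0]
            k = len(cols)
            arr[cols] = base_of[(code_of[arr[cols]] + shifts[e0 : e0 + k]) % 4]
            e0 += k
        seqs.append(arr.tobytes().decode("ascii"))

    ids = [f"{modality.name}:r{r:07d}" for r in range(N)]
    truth = pd.DataFrame(
        {
            "read_id": ids,
            "transcript_id": [transcripts[i].id for i in idx],
            "haplotype": np.where(hap == 0, "A", "B"),
            "start": starts,
        }
    )
    return ReadSet(modality=modality, ids=ids, seqs=seqs, truth=truth)


def expected_read_counts(
    transcripts: list[TranscriptTruth], modality: Modality, config: SimConfig
) -> np.ndarray:
    """Expected reads per transcript in one library (dropout not applied)."""
    w = library_weights(transcripts, modality, config)
    return modality.library_size * w / w.sum()


def emit_truth(
    transcripts: list[TranscriptTruth],
    design: tuple[Modality, ...],
    config: SimConfig,
    outdir: str | os.PathLike | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Truth tables: one row per transcript and one per modality.

    The expected RPKM column is 1e9 * expected_reads / (library_size * length).
    """
    rows = []
    exp = {m.name: expected_read_counts(transcripts, m, config) for m in design}
    for i, t in enumerate(transcripts):
        row: dict = {
            "transcript_id": t.id,
            "class": t.cls,
            "family": t.family or "",
            "length": t.length,
            "base_expression": t.base_expression,
        }
        for m in design:
            row[f"fold_{m.name}"] = t.fold[m.name]
            c = exp[m.name][i]
            row[f"expected_reads_{m.name}"] = c
            row[f"expected_rpkm_{m.name}"] = 1e9 * c / (m.library_size * t.length)
        rows.append(row)
    tr_df = pd.DataFrame(rows)
    design_df = pd.DataFrame(
        {
            "modality": [m.name for m in design],
            "phenotype": [m.phenotype for m in design],
            "time_point": [m.time_point for m in design],
            "library_size": [m.library_size for m in design],
        }
    )
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        tr_df.to_csv(os.path.join(outdir, "truth_transcripts.tsv"), sep="\t", index=False)
        design_df.to_csv(os.path.join(outdir, "truth_design.tsv"), sep="\t", index=False)
    return tr_df, design_df


def write_transcripts_fasta(
    transcripts: list[TranscriptTruth], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}_hapA class={t.cls}\n{t.hapA_seq}\n")
            fh.write(f">{t.id}_hapB class={t.cls}\n{t.hapB_seq}\n")


# ---------------------------------------------------------------------------
# Synthetic functional annotation: a miniature GO DAG and planted enrichment.

GO_ROOT = "GO:0008150"

_SYN_TERMS: dict[str, tuple[str, tuple[str, ...]]] = {
    GO_ROOT: ("biological_process", ()),
    "GO:0050896": ("response to stimulus", (GO_ROOT,)),
    "GO:0006950": ("response to stress", ("GO:0050896",)),
    "GO:0042221": ("response to chemical", ("GO:0050896",)),
    "GO:0009636": ("response to toxic substance", ("GO:0042221",)),
    "GO:0006979": ("response to oxidative stress", ("GO:0006950",)),
    "GO:0008152": ("metabolic process", (GO_ROOT,)),
    "GO:0044281": ("small molecule metabolic process", ("GO:0008152",)),
    "GO:0009082": ("branched-chain amino acid biosynthetic process", ("GO:0044281",)),
    "GO:0015979": ("photosynthesis", ("GO:0008152",)),
    "GO:0006412": ("translation", ("GO:0008152",)),
    "GO:0006468": ("protein phosphorylation", ("GO:0008152",)),
    "GO:0006810": ("transport", (GO_ROOT,)),
    "GO:0015893": ("drug transport", ("GO:0006810",)),
    "GO:0055085": ("transmembrane transport", ("GO:0006810",)),
}

#: Per effect class: the leaf term over-represented among its transcripts.
PLANTED_TERMS = {
    "common_up": ("GO:0009636", "GO:0009082"),
    "common_down": ("GO:0015979",),
    "abundant_down": ("GO:0015979",),
    "S_specific_up": ("GO:0006468",),
}

_BACKGROUND_TERMS = ("GO:0006412", "GO:0055085", "GO:0006979", "GO:0015893")


def synthetic_go(
    transcripts: list[TranscriptTruth], config: SimConfig
) -> tuple[dict, dict, dict[str, set[str]]]:
    """(terms, parents, transcript->GO annotations) with planted enrichment.

    Planted-class transcripts receive their class's leaf term with probability
    0.7; every transcript independently receives background terms at rate 0.3.
    """
    rng = _rng(config, "go")
    terms = {tid: (name, "biological_process") for tid, (name, _) in _SYN_TERMS.items()}
    parents = {tid: set(par) for tid, (_, par) in _SYN_TERMS.items()}
    ann: dict[str, set[str]] = {}
    for t in transcripts:
        got: set[str] = set()
        for term in PLANTED_TERMS.get(t.cls, ()):
            if rng.random() < 0.7:
                got.add(term)
        if rng.random() < 0.3:
            got.add(str(rng.choice(_BACKGROUND_TERMS)))
        if got:
            ann[t.id] = got
    return terms, parents, ann


def write_obo(terms: dict, parents: dict, path: str | os.PathLike) -> None:
    """Write a minimal OBO file ([Term] stanzas with id/name/namespace/is_a)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go-synthetic\n\n")
        for tid in sorted(terms):
            name, ns = terms[tid]
            fh.write(f"[Term]\nid: {tid}\nname: {name}\nnamespace: {ns}\n")
            for p in sorted(parents.get(tid, ())):
                fh.write(f"is_a: {p} ! {terms[p][0]}\n")
            fh.write("\n")


def synthetic_markers(
    transcripts: list[TranscriptTruth], config: SimConfig, n_per_group: int = 12
) -> pd.DataFrame:
    """A transcriptional-marker panel referencing planted transcripts.

    Group 1 markers point at common-response transcripts with the matching
    reference direction; group 2 markers point at stable transcripts (their
    reference direction will generally not be reproduced); a few markers
    reference silenced transcripts and so have no recoverable homolog.
    """
    by_cls: dict[str, list[TranscriptTruth]] = {}
    for t in transcripts:
        by_cls.setdefault(t.cls, []).append(t)
    rows = []
    i = 1

    def add(tr, group, direction):
        nonlocal i
        rows.append(
            {
                "marker_id": f"ATSIM{i:04d}",
                "group": group,
                "direction": direction,
                "transcript_id": tr.id,
            }
        )
        i += 1

    for tr in by_cls.get("common_up", [])[:n_per_group]:
        add(tr, 1, "up")
    for tr in by_cls.get("common_down", [])[:n_per_group]:
        add(tr, 1, "down")
    for tr in by_cls.get("stable", [])[:n_per_group]:
        add(tr, 2, "up")
    for tr in by_cls.get("low_expression", [])[:3]:
        add(tr, 2, "up")
    return pd.DataFrame(rows)
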