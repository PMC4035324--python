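"""Synthetic gene catalogs, four-stage expression truths, and tag libraries.

The generator emulates the study design the pipeline targets: a catalog of
roughly 10^4 genes, four successive developmental-stage libraries of several
million 21-mer tags each, an expression truth with stage-specific on/off
genes and designed fold-change classes (2-4x, 4-8x, >=8x, both directions)
at each stage transition, and independent per-base substitution errors.
Reads are emitted directly as 21-mer tags (the CATG anchor plus 17 bases);
raw-read artefacts are modelled by an optional malformed-read injection
(adaptor-only and wrong-length reads) so the cleaning stage has work to do.

Randomness derives from one root seed: stream k of
``numpy.random.SeedSequence(seed)`` is used for the catalog (k=0), the truth
(k=1), and each stage library (k=2+stage_index), so every piece is
independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationError
from .reads import RawTagReads
from .reference import ANCHOR, TAG_LENGTH, GeneCatalog, extract_canonical_tag

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_STAGES = ("BU", "EG", "EL", "MA")
TRANSITIONS = ("T1", "T2", "T3")
DE_CLASSES = ("up2-4", "up4-8", "up8+", "down2-4", "down4-8", "down8+", "on", "off")
_FOLD_INTERVALS = {"2-4": (2.0, 4.0), "4-8": (4.0, 8.0), "8+": (8.0, 16.0)}

#: Differential design applied to every transition by default.  Magnitudes
#: follow the empirical shape of mushroom stipe development profiles: most
#: DEGs change 2-4 fold, larger classes and outright on/off switching are
#: progressively rarer; roughly 9% of the catalog is differential per
#: transition.
DEFAULT_DE_DESIGN: dict[str, float] = {
    "up2-4": 0.040,
    "up4-8": 0.012,
    "up8+": 0.008,
    "down2-4": 0.020,
    "down4-8": 0.006,
    "down8+": 0.004,
    "on": 0.004,
    "off": 0.004,
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults describe the emulated study: ~10^4 genes, four stages, several
    million tags per library, Illumina-scale substitution error.
    """

    n_genes: int = 10_000
    gene_length_range: tuple[int, int] = (300, 3000)
    stages: tuple[str, str, str, str] = DEFAULT_STAGES
    library_sizes: tuple[int, ...] = (5_000_000,) * 4
    error_rate: float = 0.01
    frac_no_catg: float = 0.03
    de_design: Mapping[str, Mapping[str, float]] | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DE_DESIGN)
    )
    stage_specific_frac: float = 0.05
    malformed_frac: float = 0.0
    abundance_sigma: float = 1.5  # lognormal sd of baseline expression
    seed: int = 0

    def per_transition_design(self) -> dict[str, dict[str, float]]:
        """Normalize de_design to {transition: {class: fraction}}."""
        design = dict(self.de_design)
        if design and all(k in TRANSITIONS for k in design):
            out = {t: dict(design.get(t, {})) for t in TRANSITIONS}
        else:
            out = {t: dict(design) for t in TRANSITIONS}
        for t, d in out.items():
            unknown = set(d) - set(DE_CLASSES)
            if unknown:
                raise ConfigError(f"{t}: unknown DE classes {sorted(unknown)}")
            for c in DE_CLASSES:
                d.setdefault(c, 0.0)
        return out

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if lo > hi or lo < 30:
            raise ConfigError(
                f"invalid gene_length_range ({lo}, {hi}): need 30 <= min <= max"
            )
        if len(self.stages) != 4:
            raise ConfigError("exactly 4 stages required")
        if len(self.library_sizes) != len(self.stages):
            raise ConfigError("one library size per stage required")
        if any(s < 1 for s in self.library_sizes):
            raise ConfigError("library sizes must be positive")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ConfigError("error_rate must lie in [0, 0.05]")
        if not 0.0 <= self.frac_no_catg < 1.0:
            raise ConfigError("frac_no_catg must lie in [0, 1)")
        if not 0.0 <= self.stage_specific_frac < 1.0:
            raise ConfigError("stage_specific_frac must lie in [0, 1)")
        if not 0.0 <= self.malformed_frac < 1.0:
            raise ConfigError("malformed_frac must lie in [0, 1)")
        for t, d in self.per_transition_design().items():
            if any(f < 0 for f in d.values()):
                raise ConfigError(f"{t}: negative DE fraction")
            if sum(d.values()) >= 1.0:
                raise ConfigError(f"{t}: DE fractions must sum to < 1")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["gene_length_range"] = tuple(raw["gene_length_range"])
        raw["stages"] = tuple(raw["stages"])
        raw["library_sizes"] = tuple(raw["library_sizes"])
        return cls(**raw)


def _stream_rng(seed: int, stream: int) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(stream + 1)
    return np.random.default_rng(children[stream])


def _strip_catg(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Destroy every CATG occurrence by mutating its G."""
    s = seq.tobytes()
    while True:
        pos = s.find(b"CATG")
        if pos == -1:
            break
        arr = np.frombuffer(s, dtype=np.uint8).copy()
        # replace G with A/C/T
        arr[pos + 3] = rng.choice(_BASES[np.array([0, 1, 3])])
        s = arr.tobytes()
    return np.frombuffer(s, dtype=np.uint8)


def generate_catalog(config: SimulationConfig) -> GeneCatalog:
    """Generate a random gene catalog honouring the no-CATG design fraction.

    Exactly ``floor(frac_no_catg * n_genes)`` genes contain no CATG at all;
    every other gene is guaranteed at least one CATG with >= 17 downstream
    bases (a site is planted near the 3' end when chance did not supply one).
    Deterministic given the config seed.
    """
    config.validate()
    rng = _stream_rng(config.seed, 0)
    lo, hi = config.gene_length_range
    n_no_catg = math.floor(config.frac_no_catg * config.n_genes)
    no_catg_idx = set(
        rng.choice(config.n_genes, size=n_no_catg, replace=False).tolist()
    )
    width = len(str(config.n_genes))
    records = []
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(_BASES, size=length)
        if i in no_catg_idx:
            seq = _strip_catg(seq, rng)
        else:
            s = seq.tobytes().decode()
            if extract_canonical_tag(s) is None:
                # plant an anchored site with a full 17-base tail
                seq[length - TAG_LENGTH : length - TAG_LENGTH + 4] = np.frombuffer(
                    ANCHOR.encode(), dtype=np.uint8
                )
        records.append((f"g{i:0{width}d}", seq.tobytes().decode()))
    return GeneCatalog(records)


@dataclass
class TruthTable:
    """Ground-truth expression for recovery tests.

    ``abundance`` holds per-stage relative abundances (each stage column
    sums to 1 over expressed genes); ``labels`` holds the designed
    differential class per transition (``none``, ``up2-4`` ... ``off``);
    ``designed_fold`` holds the drawn fold factor (later/earlier, before
    per-stage renormalization) for finite DE classes, NaN elsewhere.
    """

    abundance: pd.DataFrame  # genes x stages
    labels: pd.DataFrame  # genes x transitions
    designed_fold: pd.DataFrame  # genes x transitions

    @property
    def stages(self) -> list[str]:
        return list(self.abundance.columns)

    def expressed(self, stage: str) -> pd.Index:
        col = self.abundance[stage]
        return col.index[col > 0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.concat(
            [
                self.abundance.add_prefix("abundance_"),
                self.labels.add_prefix("label_"),
                self.designed_fold.add_prefix("fold_"),
            ],
            axis=1,
        )
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def generate_truth(config: SimulationConfig, catalog: GeneCatalog) -> TruthTable:
    """Draw a four-stage expression truth with the designed DE structure.

    Genes are partitioned disjointly into: per-transition DE classes (counts
    ``floor(fraction * n_genes)`` each, folds drawn uniformly inside the
    class interval, persisting into later stages), stage-specific genes
    (expressed in exactly one stage), and constitutive genes with identical
    pre-normalization abundance in all stages.  Genes without a CATG site,
    and hence without an extractable tag, have abundance 0 everywhere.
    """
    config.validate()
    rng = _stream_rng(config.seed, 1)
    gene_ids = catalog.gene_ids
    n = len(gene_ids)
    stages = list(config.stages)
    design = config.per_transition_design()

    taggable = np.array(
        [extract_canonical_tag(catalog[g]) is not None for g in gene_ids]
    )
    pool = rng.permutation(np.flatnonzero(taggable))
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        if cursor + k > len(pool):
            raise ConfigError(
                "DE design + stage-specific fractions exceed the taggable genes"
            )
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    base = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    # multiplier matrix: per-gene per-stage factor applied to the baseline
    mult = np.ones((n, 4))
    mult[~taggable] = 0.0
    labels = pd.DataFrame("none", index=gene_ids, columns=list(TRANSITIONS))
    folds = pd.DataFrame(np.nan, index=gene_ids, columns=list(TRANSITIONS))

    for t_idx, t in enumerate(TRANSITIONS):
        for cls in DE_CLASSES:
            k = math.floor(design[t][cls] * config.n_genes)
            if k == 0:
                continue
            idx = take(k)
            labels.iloc[idx, t_idx] = cls
            if cls == "on":
                mult[idx, : t_idx + 1] = 0.0
            elif cls == "off":
                mult[idx, t_idx + 1 :] = 0.0
            else:
                up = cls.startswith("up")
                lo, hi = _FOLD_INTERVALS[cls[2:] if up else cls[4:]]
                f = rng.uniform(lo, hi, size=k)
                factor = f if up else 1.0 / f
                mult[idx, t_idx + 1 :] *= factor[:, None]
                folds.iloc[idx, t_idx] = factor

    # stage-specific genes: expressed in exactly one stage, spread evenly
    n_ss = math.floor(config.stage_specific_frac * config.n_genes)
    per_stage = [n_ss // 4 + (1 if s < n_ss % 4 else 0) for s in range(4)]
    for s_idx, k in enumerate(per_stage):
        if k == 0:
            continue
        idx = take(k)
        keep = np.zeros(4, dtype=bool)
        keep[s_idx] = True
        mult[np.ix_(idx, np.flatnonzero(~keep))] = 0.0
        # induced on/off labels at the flanking transitions
        if s_idx > 0:
            labels.iloc[idx, s_idx - 1] = "on"
        if s_idx < 3:
            labels.iloc[idx, s_idx] = "off"

    raw = base[:, None] * mult
    sums = raw.sum(axis=0)
    if np.any(sums <= 0):
        raise ConfigError("a stage ended up with no expressed genes")
    abundance = pd.DataFrame(raw / sums, index=gene_ids, columns=stages)
    return TruthTable(abundance=abundance, labels=labels, designed_fold=folds)


_ADAPTOR_READ = b"TCGTATGCCGTCTTCTGCTTG"  # 21 bp, contains no CATG


def simulate_library(
    catalog: GeneCatalog,
    truth: TruthTable,
    stage: str,
    size: int,
    error_rate: float,
    seed: int,
    malformed_frac: float = 0.0,
) -> RawTagReads:
    """Simulate one stage library of ``size`` raw 21-mer tag reads.

    Reads are drawn multinomially from the stage's truth abundances as each
    gene's canonical tag, then every base is substituted independently with
    probability ``error_rate``.  A fraction ``malformed_frac`` of reads is
    replaced by cleaning fodder: half adaptor-only reads, half wrong-length
    fragments of real tags.  Deterministic given the seed.
    """
    if stage not in truth.stages:
        raise SimulationError(f"stage {stage!r} not in the truth table")
    rng = np.random.default_rng(seed)
    probs = truth.abundance[stage]
    expressed = probs.index[probs > 0]
    tags = []
    for gene in expressed:
        tag = extract_canonical_tag(catalog[gene])
        if tag is None:
            raise SimulationError(
                f"expressed gene {gene!r} has no extractable canonical tag"
            )
        tags.append(tag)
    tag_matrix = (
        np.frombuffer("".join(tags).encode(), dtype=np.uint8).reshape(len(tags), TAG_LENGTH)
        if tags
        else np.empty((0, TAG_LENGTH), dtype=np.uint8)
    )
    if len(tags) == 0:
        raise SimulationError(f"no expressed genes in stage {stage!r}")

    counts = rng.multinomial(size, probs.loc[expressed].to_numpy())
    reads = np.repeat(tag_matrix, counts, axis=0)

    if error_rate > 0.0:
        mask = rng.random(reads.shape) < error_rate
        n_err = int(mask.sum())
        if n_err:
            # substitute with one of the three other bases, uniformly
            code = np.zeros(256, dtype=np.uint8)  # byte -> 0..3
            code[_BASES] = np.arange(4)
            current = code[reads[mask]]
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            reads[mask] = _BASES[(current + shift) % 4]

    if malformed_frac > 0.0:
        n_bad = math.floor(malformed_frac * size)
        bad_idx = rng.choice(size, size=n_bad, replace=False)
        half = n_bad // 2
        seq_list = [r.tobytes() for r in reads]
        adaptor = _ADAPTOR_READ
        for j, ridx in enumerate(bad_idx):
            if j < half:
                seq_list[ridx] = adaptor
            else:
                # wrong length: truncate to 15 bp or extend to 25 bp
                if rng.random() < 0.5:
                    seq_list[ridx] = seq_list[ridx][:15]
                else:
                    extra = rng.choice(_BASES, size=4).tobytes()
                    seq_list[ridx] = seq_list[ridx] + extra
        sequences = np.asarray(seq_list, dtype="S")
    else:
        sequences = reads.view(f"S{TAG_LENGTH}").ravel()

    return RawTagReads(sequences, qualities=None, library_id=stage)


def simulate_all_libraries(
    config: SimulationConfig,
    catalog: GeneCatalog,
    truth: TruthTable,
) -> dict[str, RawTagReads]:
    """Simulate every stage library with its documented seed stream."""
    out = {}
    for s_idx, stage in enumerate(config.stages):
        rng_seed = np.random.SeedSequence(config.seed).spawn(6)[2 + s_idx]
        out[stage] = simulate_library(
            catalog,
            truth,
            stage,
            size=config.library_sizes[s_idx],
            error_rate=config.error_rate,
            seed=rng_seed.generate_state(1)[0] % (2**31),
            malformed_frac=config.malformed_frac,
        )
    return out
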