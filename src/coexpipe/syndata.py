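"""Synthetic time-course RNA-seq data with planted ground truth.

The generator emulates a short hormone-treatment time course (three
libraries at 0/2/4 h by default, one library per time point, no
replicates) sampled at bulk depth:

* per-gene baseline log2 abundance drawn from a normal distribution,
* planted co-expression modules that share a latent log2 profile across
  time points (plus per-gene, per-time normal noise),
* planted differentially expressed genes with a specified log2 fold
  change between two time points,
* negative-binomial counts around the latent means, and
* a flat gene -> term annotation map in which each planted module carries
  one enriched term.

Expected counts of gene g in sample s are ``library_size[s] * a[g, s]``
where ``a[:, s]`` is the per-sample relative-abundance vector implied by
the latent log2 expression (2**z, normalized to sum to one per sample),
so simulated depth is exactly the configured library size in expectation.

The negative-binomial ``dispersion`` is the shape (size) parameter r of
the NB(r, p) parameterization with variance ``mu + mu**2 / r``: large r
approaches Poisson, small r is strongly overdispersed.  ``math.inf`` is
accepted and yields exact Poisson counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .quantify import CountMatrix

__all__ = [
    "ModuleSpec",
    "DeSpec",
    "SimulationConfig",
    "GroundTruth",
    "AnnotationMap",
    "simulate_counts",
    "simulate_annotation",
    "write_annotation_tsv",
    "read_annotation_tsv",
]

#: time-point labels used when the config does not override them
DEFAULT_LABELS = ("0h", "2h", "4h")


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expressed module.

    ``profile`` is the latent log2-expression offset added at each time
    point, shared by every member; ``within_noise_sd`` is the sd (log2
    units) of per-gene, per-time-point deviations from that profile.
    """

    size: int
    profile: tuple[float, ...]
    within_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if self.within_noise_sd < 0:
            raise ValueError("within_noise_sd must be >= 0")
        object.__setattr__(self, "profile", tuple(float(v) for v in self.profile))


@dataclass(frozen=True)
class DeSpec:
    """A planted differentially expressed gene.

    The latent log2 abundance of ``gene_index`` at time ``comparison[1]``
    is offset by ``log2_fc`` relative to time ``comparison[0]``.
    """

    gene_index: int
    comparison: tuple[int, int] = (0, 1)
    log2_fc: float = 2.0

    def __post_init__(self) -> None:
        if self.comparison[0] == self.comparison[1]:
            raise ValueError("comparison time points must be distinct")


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment."""

    n_genes: int = 500
    n_timepoints: int = 3
    library_sizes: list[int] = field(default_factory=lambda: [1_000_000] * 3)
    gene_length_range: tuple[int, int] = (500, 3000)
    nb_dispersion: float = 10.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    modules: list[ModuleSpec] = field(default_factory=list)
    de_genes: list[DeSpec] = field(default_factory=list)
    sample_labels: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        if len(self.library_sizes) != self.n_timepoints:
            raise ValueError("one library size per time point required")
        if any(ls < 1 for ls in self.library_sizes):
            raise ValueError("library sizes must be positive")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid gene_length_range")
        if not self.nb_dispersion > 0:
            raise ValueError("nb_dispersion must be > 0")
        for m in self.modules:
            if len(m.profile) != self.n_timepoints:
                raise ValueError(
                    "module profile length must equal n_timepoints"
                )
        if self.sample_labels is None:
            if self.n_timepoints == 3:
                self.sample_labels = list(DEFAULT_LABELS)
            else:
                self.sample_labels = [f"t{i}" for i in range(self.n_timepoints)]
        if len(self.sample_labels) != self.n_timepoints:
            raise ValueError("one sample label per time point required")
        self._validate_indices()

    def _validate_indices(self) -> None:
        n_module_genes = sum(m.size for m in self.modules)
        if n_module_genes > self.n_genes:
            raise ValueError("modules require more genes than n_genes")
        seen: set[int] = set()
        for spec in self.de_genes:
            g = spec.gene_index
            if not 0 <= g < self.n_genes:
                raise ValueError(f"DE gene index {g} out of range")
            if g < n_module_genes:
                raise ValueError(
                    f"DE gene index {g} collides with a planted module "
                    f"(module genes occupy indices 0..{n_module_genes - 1})"
                )
            if g in seen:
                raise ValueError(f"duplicate DE gene index {g}")
            seen.add(g)
            lo, hi = spec.comparison
            for t in (lo, hi):
                if not 0 <= t < self.n_timepoints:
                    raise ValueError(f"DE comparison time {t} out of range")


@dataclass
class GroundTruth:
    """What was planted: module membership, DE calls, enriched terms."""

    module_membership: dict[str, int]
    de_calls: set[tuple[str, tuple[int, int], str]]
    enriched_terms: dict[int, set[str]]

    def module_genes(self, module_id: int) -> list[str]:
        return [g for g, m in self.module_membership.items() if m == module_id]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_membership": self.module_membership,
            "de_calls": sorted(
                [g, list(c), d] for g, c, d in self.de_calls
            ),
            "enriched_terms": {
                str(m): sorted(ts) for m, ts in self.enriched_terms.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


@dataclass
class AnnotationMap:
    """Flat gene -> set-of-terms annotation over a background universe."""

    gene_terms: dict[str, set[str]]
    term_universe: set[str]
    background: list[str]

    def __post_init__(self) -> None:
        unknown = set(self.gene_terms) - set(self.background)
        if unknown:
            raise ValueError(
                f"annotated genes missing from background: {sorted(unknown)[:5]}"
            )

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


def _planted_term(module_id: int) -> str:
    return f"TERM:{7000000 + module_id:07d}"


def _latent_log2(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent log2 abundance per gene per time point."""
    base = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_genes
    )
    z = np.tile(base[:, None], (1, config.n_timepoints))
    g0 = 0
    for m in config.modules:
        block = slice(g0, g0 + m.size)
        z[block, :] += np.asarray(m.profile)[None, :]
        if m.within_noise_sd > 0:
            z[block, :] += rng.normal(
                0.0, m.within_noise_sd, size=(m.size, config.n_timepoints)
            )
        g0 += m.size
    for spec in config.de_genes:
        z[spec.gene_index, spec.comparison[1]] += spec.log2_fc
    return z


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw one synthetic count matrix and its ground truth.

    Deterministic: identical config (including seed) gives bit-identical
    output.  Counts are negative binomial around ``library_size * a`` where
    ``a`` is the per-sample relative abundance implied by the latent log2
    expression.
    """
    rng = np.random.default_rng(config.seed)
    lengths = rng.integers(
        config.gene_length_range[0],
        config.gene_length_range[1] + 1,
        size=config.n_genes,
    )
    z = _latent_log2(config, rng)
    weights = np.exp2(z)
    rel = weights / weights.sum(axis=0, keepdims=True)
    mu = rel * np.asarray(config.library_sizes, dtype=float)[None, :]

    if math.isinf(config.nb_dispersion):
        counts = rng.poisson(mu)
    else:
        r = config.nb_dispersion
        # NB via gamma-Poisson mixture: keeps mean exactly mu for any r
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam)

    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    cm = CountMatrix(
        gene_ids=gene_ids,
        lengths=lengths,
        counts=counts.astype(np.int64),
        sample_labels=list(config.sample_labels),
        library_sizes=np.asarray(config.library_sizes),
    )

    membership: dict[str, int] = {}
    g0 = 0
    for mid, m in enumerate(config.modules):
        for g in range(g0, g0 + m.size):
            membership[gene_ids[g]] = mid
        g0 += m.size
    de_calls = {
        (
            gene_ids[s.gene_index],
            tuple(s.comparison),
            "up" if s.log2_fc > 0 else "down",
        )
        for s in config.de_genes
    }
    enriched = {mid: {_planted_term(mid)} for mid in range(len(config.modules))}
    return cm, GroundTruth(membership, de_calls, enriched)


def simulate_annotation(
    truth: GroundTruth,
    genes: list[str],
    n_terms: int,
    background_rate: float,
    enriched_rate: float,
    seed: int,
) -> AnnotationMap:
    """Annotate genes so each planted module's term is enriched in it.

    Members of a module carrying an enriched term receive that term with
    probability ``enriched_rate``; every other (gene, term) pair is
    annotated at ``background_rate``.  Terms beyond the planted ones are
    pure background.
    """
    if not 0 <= background_rate <= 1 or not 0 <= enriched_rate <= 1:
        raise ValueError("annotation rates must lie in [0, 1]")
    if background_rate >= enriched_rate:
        raise ValueError("background_rate must be strictly below enriched_rate")
    planted = {t for ts in truth.enriched_terms.values() for t in ts}
    n_planted = len(planted)
    if n_terms < n_planted:
        raise ValueError(
            f"n_terms={n_terms} smaller than {n_planted} planted terms"
        )
    terms = sorted(planted) + [
        f"TERM:{1000000 + i:07d}" for i in range(n_terms - n_planted)
    ]
    term_of_module = {
        mid: sorted(ts) for mid, ts in truth.enriched_terms.items()
    }

    rng = np.random.default_rng(seed)
    draw = rng.random(size=(len(genes), len(terms)))
    rate = np.full((len(genes), len(terms)), background_rate)
    term_col = {t: j for j, t in enumerate(terms)}
    for gi, g in enumerate(genes):
        mid = truth.module_membership.get(g)
        if mid is None:
            continue
        for t in term_of_module.get(mid, ()):
            rate[gi, term_col[t]] = enriched_rate
    hits = draw < rate

    gene_terms = {
        g: {terms[j] for j in np.flatnonzero(hits[gi])}
        for gi, g in enumerate(genes)
        if hits[gi].any()
    }
    return AnnotationMap(
        gene_terms=gene_terms, term_universe=set(terms), background=list(genes)
    )


def write_annotation_tsv(annotation: AnnotationMap, path: str | Path) -> None:
    """Two-column TSV, one ``gene<TAB>term`` row per association."""
    with open(path, "w") as fh:
        for g in annotation.background:
            for t in sorted(annotation.gene_terms.get(g, ())):
                fh.write(f"{g}\t{t}\n")


def read_annotation_tsv(
    path: str | Path, background: list[str] | None = None
) -> AnnotationMap:
    gene_terms: dict[str, set[str]] = {}
    terms: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            g, t = line.split("\t")
            gene_terms.setdefault(g, set()).add(t)
            terms.add(t)
    if background is None:
        background = sorted(gene_terms)
    return AnnotationMap(gene_terms=gene_terms, term_universe=terms, background=background)
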