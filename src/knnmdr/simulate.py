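"""Case-control epistasis simulator with zero marginal effects.

The generator follows a block-resampling design: a small synthetic
founder panel with tunable neighbor LD stands in for a real genotype
panel; simulated individuals are mosaics of founder blocks; G causal
markers get a multi-locus penetrance table constrained so that every
causal locus's frequency-weighted marginal penetrance equals the
prevalence — interactions without marginal effects.  Phenotypes are
uniform-deviate draws against the table, case/control quotas are filled
exactly, and markers can optionally be thinned (one of each consecutive
pair discarded) so causal variants may or may not remain genotyped.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import null_space

from .genotype_io import GenotypeMatrix, MarkerMap, PhenotypeVector

__all__ = [
    "BasePanel",
    "PenetranceTable",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_base_panel",
    "resample_individuals",
    "hwe_genotype_freqs",
    "build_penetrance_table",
    "assign_phenotypes",
    "thin_markers",
    "simulate_dataset",
]


@dataclasses.dataclass
class BasePanel:
    """Founder genotypes used as the block-resampling reservoir."""

    genotypes: np.ndarray  # (n_founders, n_markers) counts in {0,1,2}
    maf_min: float
    rho: float

    @property
    def n_founders(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def genotype_frequencies(self, marker: int) -> np.ndarray:
        """Empirical (P0, P1, P2) of one marker among the founders.

        Block resampling copies founder genotypes uniformly, so this is
        exactly the sampling distribution of the marker in simulated
        individuals.
        """
        return np.bincount(self.genotypes[:, marker], minlength=3) / self.n_founders


def simulate_base_panel(
    n_founders: int = 197,
    n_markers: int = 2000,
    maf_min: float = 0.3,
    rho: float = 0.5,
    seed: int | np.random.Generator = 0,
    max_retries: int = 50,
) -> BasePanel:
    """Generate a founder panel with first-order Markov LD along markers.

    Haplotype alleles follow a chain where each allele is copied from its
    left neighbor with probability ``rho`` and otherwise drawn fresh at
    that marker's frequency (uniform in ``[maf_min, 0.5]``).  Markers
    whose realized sample MAF falls below ``maf_min`` are redrawn as
    independent columns (bounded retries).
    """
    if n_founders < 1 or n_markers < 1:
        raise ValueError("panel dimensions must be positive")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = rng.uniform(maf_min, 0.5, size=n_markers)

    haplotypes = np.empty((2 * n_founders, n_markers), dtype=np.int8)
    fresh = rng.random((2 * n_founders, n_markers)) < freqs[None, :]
    copy = rng.random((2 * n_founders, n_markers)) < rho
    haplotypes[:, 0] = fresh[:, 0]
    for m in range(1, n_markers):
        haplotypes[:, m] = np.where(copy[:, m], haplotypes[:, m - 1], fresh[:, m])

    genotypes = haplotypes[0::2] + haplotypes[1::2]
    for _ in range(max_retries):
        p = genotypes.mean(axis=0) / 2.0
        bad = np.flatnonzero(np.minimum(p, 1 - p) < maf_min)
        if bad.size == 0:
            break
        f = rng.uniform(maf_min, 0.5, size=bad.size)
        redraw = rng.binomial(1, f, size=(2 * n_founders, bad.size)).astype(np.int8)
        genotypes[:, bad] = redraw[0::2] + redraw[1::2]
    else:
        raise RuntimeError(
            f"could not reach MAF >= {maf_min} for all markers after "
            f"{max_retries} retries; try a smaller maf_min or more founders"
        )
    return BasePanel(genotypes, maf_min, rho)


def resample_individuals(
    panel: BasePanel,
    block_size: int,
    n_individuals: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Build individuals as mosaics of founder genotype blocks.

    For each individual and each block of ``block_size`` consecutive
    markers, one founder is drawn uniformly and its block genotype is
    copied verbatim; draws are independent across blocks.  A trailing
    remainder block is allowed.  Within-block LD of the panel is
    preserved exactly; across-block LD is broken.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = list(range(0, panel.n_markers, block_size)) + [panel.n_markers]
    n_blocks = len(edges) - 1
    founders = rng.integers(0, panel.n_founders, size=(n_individuals, n_blocks))
    out = np.empty((n_individuals, panel.n_markers), dtype=np.int8)
    for b in range(n_blocks):
        lo, hi = edges[b], edges[b + 1]
        out[:, lo:hi] = panel.genotypes[founders[:, b], lo:hi]
    return out


def hwe_genotype_freqs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (P0, P1, P2) at a given MAF."""
    p = maf
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


@dataclasses.dataclass
class PenetranceTable:
    """Multi-locus penetrances with zero marginal effect at every locus.

    ``mp`` has shape ``(3,) * n_loci`` and is indexed by minor-allele
    counts; ``genotype_freqs`` (``(n_loci, 3)``) are the per-locus
    genotype probabilities under which the marginals vanish.
    """

    mp: np.ndarray
    prevalence: float
    genotype_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.mp = np.asarray(self.mp, dtype=float)
        self.genotype_freqs = np.atleast_2d(np.asarray(self.genotype_freqs, dtype=float))
        if self.mp.shape != (3,) * self.n_loci:
            raise ValueError("mp must have shape (3,)*n_loci")
        if np.any(self.mp < 0) or np.any(self.mp > 1):
            raise ValueError("penetrances must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.genotype_freqs.shape[0]

    def marginal(self, locus: int) -> np.ndarray:
        """Frequency-weighted penetrance of each genotype at one locus."""
        weighted = self.mp
        for j in range(self.n_loci):
            if j == locus:
                continue
            shape = [1] * self.n_loci
            shape[j] = 3
            weighted = weighted * self.genotype_freqs[j].reshape(shape)
        axes = tuple(j for j in range(self.n_loci) if j != locus)
        return weighted.sum(axis=axes)

    def max_marginal_residual(self) -> float:
        return max(
            float(np.abs(self.marginal(i) - self.prevalence).max())
            for i in range(self.n_loci)
        )

    def to_dict(self) -> dict:
        return {
            "prevalence": self.prevalence,
            "mp": self.mp.tolist(),
            "genotype_freqs": self.genotype_freqs.tolist(),
        }


def _marginal_operator(genotype_freqs: np.ndarray) -> np.ndarray:
    """Rows: one per (locus, genotype); columns: flattened multi-locus cells.

    Entry = product of the other loci's genotype frequencies if the cell
    matches the row's genotype at the row's locus, else 0.  ``A @ mp``
    then lists all frequency-weighted marginal penetrances.
    """
    G = genotype_freqs.shape[0]
    cells = np.array(np.meshgrid(*[range(3)] * G, indexing="ij")).reshape(G, -1)
    A = np.zeros((3 * G, 3**G))
    for i in range(G):
        others = [j for j in range(G) if j != i]
        weights = np.ones(cells.shape[1])
        for j in others:
            weights = weights * genotype_freqs[j, cells[j]]
        for k in range(3):
            A[3 * i + k, cells[i] == k] = weights[cells[i] == k]
    return A


def build_penetrance_table(
    n_loci: int,
    prevalence: float = 0.5,
    genotype_freqs: np.ndarray | Sequence[Sequence[float]] | None = None,
    effect_size: float = 0.4,
    seed: int | np.random.Generator = 0,
    n_draws: int = 16,
) -> PenetranceTable:
    """Draw a penetrance table whose marginals all equal the prevalence.

    The deviation from the constant table is drawn in the null space of
    the marginalization operator (one constraint per locus x genotype)
    and scaled so its largest absolute entry equals ``effect_size``;
    among ``n_draws`` seeded draws the one with the largest
    frequency-weighted variance is kept, which favors informative tables.
    If the scale would push a penetrance outside ``[0, 1]`` it is clipped
    with a warning.  ``n_loci == 1`` admits only the constant table.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if genotype_freqs is None:
        genotype_freqs = np.tile(hwe_genotype_freqs(0.3), (n_loci, 1))
    genotype_freqs = np.atleast_2d(np.asarray(genotype_freqs, dtype=float))
    if genotype_freqs.shape != (n_loci, 3):
        raise ValueError("genotype_freqs must have shape (n_loci, 3)")
    if np.any(genotype_freqs < 0) or not np.allclose(genotype_freqs.sum(axis=1), 1.0):
        raise ValueError("each locus's genotype frequencies must sum to 1")

    constant = np.full((3,) * n_loci, prevalence)
    if effect_size == 0.0:
        return PenetranceTable(constant, prevalence, genotype_freqs)

    A = _marginal_operator(genotype_freqs)
    N = null_space(A)
    if N.shape[1] == 0:
        raise ValueError(
            "no non-constant zero-marginal table exists for a single locus; "
            "use effect_size=0 or n_loci >= 2"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cell_w = np.ones(3**n_loci)
    cells = np.array(np.meshgrid(*[range(3)] * n_loci, indexing="ij")).reshape(n_loci, -1)
    for j in range(n_loci):
        cell_w = cell_w * genotype_freqs[j, cells[j]]

    bound = min(prevalence, 1.0 - prevalence)
    scale = effect_size
    if effect_size > bound:
        warnings.warn(
            f"effect_size {effect_size} clipped to {bound} to keep "
            "penetrances in [0, 1]"
        )
        scale = bound

    best_e, best_var = None, -1.0
    for _ in range(max(1, n_draws)):
        e = N @ rng.standard_normal(N.shape[1])
        peak = np.abs(e).max()
        if peak == 0.0:
            continue
        e = e * (scale / peak)
        var = float(cell_w @ e**2)
        if var > best_var:
            best_var, best_e = var, e
    mp = constant + best_e.reshape((3,) * n_loci)
    return PenetranceTable(np.clip(mp, 0.0, 1.0), prevalence, genotype_freqs)


def assign_phenotypes(
    values: np.ndarray,
    causal_idx: Sequence[int],
    table: PenetranceTable,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Affected iff a uniform deviate falls below the cell penetrance."""
    causal_idx = list(causal_idx)
    if len(set(causal_idx)) != len(causal_idx):
        raise ValueError("causal marker indices must be distinct")
    if len(causal_idx) != table.n_loci:
        raise ValueError("number of causal markers must match the table")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = tuple(values[:, c] for c in causal_idx)
    mp = table.mp[cells]
    return rng.random(values.shape[0]) < mp


def thin_markers(
    values: np.ndarray,
    marker_map: MarkerMap | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, MarkerMap | None, np.ndarray]:
    """Randomly discard one marker of each consecutive pair (fair coin).

    With an odd marker count the last marker is always kept.  Returns the
    thinned values, the subset map (if one was given) and the kept
    original indices, so causal positions can be traced.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = values.shape[1]
    n_pairs = M // 2
    keep_second = rng.integers(0, 2, size=n_pairs)
    kept = 2 * np.arange(n_pairs) + keep_second
    if M % 2:
        kept = np.append(kept, M - 1)
    kept = np.sort(kept)
    sub_map = marker_map.subset(kept) if marker_map is not None else None
    return values[:, kept], sub_map, kept


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """End-to-end generator settings."""

    n_causal: int = 2
    n_cases: int = 500
    n_controls: int = 500
    n_founders: int = 197
    n_markers: int = 2000
    maf_min: float = 0.3
    rho: float = 0.5
    block_size: int = 10
    effect_size: float = 0.4
    prevalence: float = 0.5
    thin: bool = True
    seed: int = 0
    causal_idx: tuple[int, ...] | None = None
    max_batches: int = 200

    def __post_init__(self) -> None:
        if self.n_causal < 0 or (self.n_causal == 1 and self.effect_size > 0):
            raise ValueError("n_causal must be 0 or >= 2 for a nonzero effect")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("case/control counts must be positive")


@dataclasses.dataclass
class SimulatedDataset:
    """Generated genotypes, phenotype and the ground-truth record."""

    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    phenotype: PhenotypeVector
    truth: dict

    def write(self, prefix: str | Path) -> None:
        from .genotype_io import write_genotypes

        prefix = Path(prefix)
        write_genotypes(prefix, self.genotypes, self.marker_map,
                        format="ped_map", phenotype=self.phenotype)
        with open(prefix.with_suffix(".truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=1)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Full pipeline: panel, mosaics, penetrance, phenotypes, thinning.

    Individuals are drawn in batches and assigned phenotypes until the
    exact case and control quotas are met (first-come).  With
    ``n_causal == 0`` phenotypes are fair coin flips and the truth record
    carries no causal markers.
    """
    root = np.random.default_rng(cfg.seed)
    panel = simulate_base_panel(
        cfg.n_founders, cfg.n_markers, cfg.maf_min, cfg.rho, seed=root
    )
    if cfg.n_causal > 0:
        if cfg.causal_idx is not None:
            causal = list(cfg.causal_idx)
            if len(causal) != cfg.n_causal:
                raise ValueError("causal_idx length must equal n_causal")
        else:
            causal = sorted(
                root.choice(cfg.n_markers, size=cfg.n_causal, replace=False).tolist()
            )
        freqs = np.stack([panel.genotype_frequencies(c) for c in causal])
        table = build_penetrance_table(
            cfg.n_causal, cfg.prevalence, freqs, cfg.effect_size, seed=root
        )
    else:
        causal, table = [], None

    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    case_rows, control_rows = [], []
    batch = max(256, 2 * (need_cases + need_controls))
    for _ in range(cfg.max_batches):
        g = resample_individuals(panel, cfg.block_size, batch, seed=root)
        if table is not None:
            affected = assign_phenotypes(g, causal, table, seed=root)
        else:
            affected = root.random(batch) < cfg.prevalence
        case_rows.append(g[affected])
        control_rows.append(g[~affected])
        if (
            sum(len(r) for r in case_rows) >= need_cases
            and sum(len(r) for r in control_rows) >= need_controls
        ):
            break
    else:
        raise RuntimeError(
            "case/control quotas unreachable within the batch budget "
            "(is the penetrance table degenerate?)"
        )
    cases = np.concatenate(case_rows)[:need_cases]
    controls = np.concatenate(control_rows)[:need_controls]
    values = np.concatenate([cases, controls])
    is_case = np.zeros(len(values), dtype=bool)
    is_case[:need_cases] = True

    marker_map = MarkerMap.default(cfg.n_markers)
    kept = np.arange(cfg.n_markers)
    if cfg.thin:
        values, marker_map, kept = thin_markers(values, marker_map, seed=root)
    pos_of = {int(orig): int(new) for new, orig in enumerate(kept)}
    causal_after = [pos_of.get(c, -1) for c in causal]

    ids = [f"ind{i + 1}" for i in range(len(values))]
    truth = {
        "config": dataclasses.asdict(cfg),
        "causal_markers": [int(c) for c in causal],
        "causal_markers_after_thinning": causal_after,
        "penetrance_table": None if table is None else table.to_dict(),
        "kept_marker_indices": kept.tolist() if cfg.thin else None,
    }
    return SimulatedDataset(
        GenotypeMatrix(values, ids),
        marker_map,
        PhenotypeVector(is_case),
        truth,
    )
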