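"""Synthetic case-control datasets with one purely epistatic SNP pair.

Each dataset emulates the standard two-locus epistasis benchmark design:
N SNPs for a balanced case/control panel in which exactly one pair of
SNPs ("X0", "X1") jointly influences disease status through a 3x3
penetrance table, while every other SNP is independent Hardy-Weinberg
noise with identical distribution in cases and controls.

The penetrance model is the hard part: the table must (a) imply a target
prevalence K = sum_ab pi_a pi_b f_ab under HWE genotype frequencies,
(b) have *zero marginal effects* — every row and column of penetrances,
averaged with HWE weights, equals K, so neither locus is individually
associated with disease — and (c) hit a target broad-sense heritability

    h2 = sum_ab pi_a pi_b (f_ab - K)^2 / (K (1 - K)).

Tables are found by rejection: draw a random 3x3 deviation table,
project it onto the marginal-effect-free subspace by HWE-weighted double
centering, rescale the deviations to the target h2, and accept when all
penetrances land in [0, 1]. The achievable h2 is bounded by maf and
prevalence; the defaults (maf 0.4, prevalence 0.25) admit the full
benchmark range h2 in [0.05, 0.3] with headroom.

Cases and controls are filled by rejection sampling: a fresh individual
with functional genotypes (a, b) becomes a case with probability f_ab,
a control otherwise, until both quotas are met — a retrospective design
that hits exact balanced counts.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data import GenotypeDataset, write_mdr

__all__ = [
    "PenetranceModel",
    "SimulationConfig",
    "MODEL_NAMES",
    "hwe_genotype_probs",
    "prevalence_of",
    "heritability_of",
    "make_penetrance_model",
    "simulate_dataset",
    "model_config",
    "write_simulation",
]

DEFAULT_MAF = 0.4
DEFAULT_PREVALENCE = 0.25
FUNCTIONAL_PAIR = ("X0", "X1")

#: The eight benchmark models: 1000 SNPs, balanced samples, one pair.
MODEL_NAMES = tuple(
    f"Epistatic_{total}_{h2}"
    for total in (400, 800)
    for h2 in ("0.05", "0.1", "0.2", "0.3")
)

_TOL = 1e-6


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    p = maf
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def prevalence_of(table: np.ndarray, maf: float) -> float:
    """Population disease probability implied by a penetrance table."""
    pi = hwe_genotype_probs(maf)
    return float(pi @ np.asarray(table, dtype=np.float64) @ pi)


def heritability_of(table: np.ndarray, maf: float) -> float:
    """Variance of penetrance around prevalence, scaled by K(1-K)."""
    table = np.asarray(table, dtype=np.float64)
    pi = hwe_genotype_probs(maf)
    k = prevalence_of(table, maf)
    if k <= 0.0 or k >= 1.0:
        raise ValueError(f"degenerate prevalence {k}")
    w = np.outer(pi, pi)
    return float((w * (table - k) ** 2).sum() / (k * (1 - k)))


@dataclass(frozen=True)
class PenetranceModel:
    """Two-locus penetrance table plus the frequencies that define it."""

    table: np.ndarray
    maf: float
    prevalence: float
    h2: float

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=np.float64)
        if t.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if ((t < 0) | (t > 1)).any():
            raise ValueError("penetrances must lie in [0, 1]")
        pi = hwe_genotype_probs(self.maf)
        k = prevalence_of(t, self.maf)
        if abs(k - self.prevalence) > 1e-9:
            raise ValueError(
                f"table implies prevalence {k}, declared {self.prevalence}"
            )
        row = t @ pi
        col = pi @ t
        if np.abs(row - k).max() > _TOL or np.abs(col - k).max() > _TOL:
            raise ValueError("model has marginal effects beyond tolerance")
        h2 = heritability_of(t, self.maf)
        if abs(h2 - self.h2) > _TOL:
            raise ValueError(f"table heritability {h2} != declared {self.h2}")
        t.setflags(write=False)
        object.__setattr__(self, "table", t)


def make_penetrance_model(
    h2: float,
    maf: float = DEFAULT_MAF,
    prevalence: float = DEFAULT_PREVALENCE,
    seed: int = 0,
    max_tries: int = 10_000,
) -> PenetranceModel:
    """Draw a marginal-effect-free penetrance table at the target h2.

    Deterministic in ``seed``. Raises when no feasible table is found,
    which signals that ``h2`` exceeds the bound set by (maf, prevalence).
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    pi = hwe_genotype_probs(maf)
    w = np.outer(pi, pi)
    target_var = h2 * prevalence * (1 - prevalence)
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        d = rng.uniform(-1.0, 1.0, size=(3, 3))
        # HWE-weighted double centering removes both marginal effects
        row = d @ pi
        col = pi @ d
        grand = pi @ d @ pi
        d = d - row[:, None] - col[None, :] + grand
        var = float((w * d**2).sum())
        if var < 1e-12:
            continue
        table = prevalence + d * np.sqrt(target_var / var)
        if ((table >= 0) & (table <= 1)).all():
            return PenetranceModel(
                table=table, maf=maf, prevalence=prevalence, h2=h2
            )
    raise ValueError(
        f"no feasible penetrance table for h2={h2} at maf={maf}, "
        f"prevalence={prevalence}: h2 exceeds the feasible bound"
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one simulated model."""

    n_snps: int = 1000
    n_cases: int = 200
    n_controls: int = 200
    h2: float = 0.1
    maf: float = DEFAULT_MAF
    prevalence: float = DEFAULT_PREVALENCE
    n_datasets: int = 100
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValueError("need at least the functional pair")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


def model_config(name: str, **overrides) -> SimulationConfig:
    """Config for a benchmark model name like ``Epistatic_400_0.1``."""
    m = re.fullmatch(r"Epistatic_(400|800)_(0\.05|0\.1|0\.2|0\.3)", name)
    if not m:
        raise ValueError(
            f"unknown model {name!r}; expected one of {', '.join(MODEL_NAMES)}"
        )
    total = int(m.group(1))
    h2 = float(m.group(2))
    defaults = dict(
        n_snps=1000, n_cases=total // 2, n_controls=total // 2,
        h2=h2, name=name,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def simulate_dataset(
    config: SimulationConfig,
    model: PenetranceModel,
    seed: int,
) -> GenotypeDataset:
    """Generate one dataset: functional pair "X0"/"X1" plus HWE noise.

    Case/control rows are filled by rejection sampling on the functional
    genotypes; noise SNPs are drawn identically for both classes. SNP
    column order is randomized so the pair is not positionally
    privileged; rows are cases first, then controls.
    """
    rng = np.random.default_rng(seed)
    pi = model.table  # penetrance lookup
    probs = hwe_genotype_probs(model.maf)
    n_cases, n_controls = config.n_cases, config.n_controls
    total = n_cases + n_controls

    cases: list[tuple[int, int]] = []
    controls: list[tuple[int, int]] = []
    mean_pen = prevalence_of(model.table, model.maf)
    # generous cap: expected draws = quota / min(K, 1-K)
    max_draws = int(50 * total / min(mean_pen, 1 - mean_pen)) + 1000
    draws = 0
    while (len(cases) < n_cases or len(controls) < n_controls):
        if draws >= max_draws:
            raise RuntimeError(
                "rejection sampler could not fill case/control quotas; "
                "penetrance model is too close to degenerate"
            )
        batch = max(64, total)
        a = rng.choice(3, size=batch, p=probs)
        b = rng.choice(3, size=batch, p=probs)
        u = rng.random(batch)
        draws += batch
        for ai, bi, ui in zip(a, b, u):
            if ui < pi[ai, bi]:
                if len(cases) < n_cases:
                    cases.append((ai, bi))
            elif len(controls) < n_controls:
                controls.append((ai, bi))

    functional = np.array(cases + controls, dtype=np.int8)
    labels = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    n_noise = config.n_snps - 2
    noise = rng.choice(3, size=(total, n_noise), p=probs).astype(np.int8)

    genotypes = np.concatenate([functional, noise], axis=1)
    names = list(FUNCTIONAL_PAIR) + [f"X{j}" for j in range(2, config.n_snps)]
    order = rng.permutation(config.n_snps)
    return GenotypeDataset(
        genotypes=genotypes[:, order],
        labels=labels,
        snp_names=tuple(names[j] for j in order),
    )


def write_simulation(config: SimulationConfig, outdir: str | Path) -> list[Path]:
    """Write ``config.n_datasets`` MDR files plus a JSON sidecar.

    Files are named ``<model>_<index>.txt``; the sidecar records the
    config, the penetrance table and every per-dataset seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    model_seed, data_root = (int(s) for s in
                             root.generate_state(2, dtype=np.uint32) & 0x7FFFFFFF)
    model = make_penetrance_model(
        config.h2, config.maf, config.prevalence, seed=model_seed
    )
    data_seeds = np.random.SeedSequence(data_root).generate_state(
        config.n_datasets, dtype=np.uint32
    ) & 0x7FFFFFFF
    stem = config.name or f"Epistatic_{config.n_cases + config.n_controls}_{config.h2}"
    paths: list[Path] = []
    for i, ds_seed in enumerate(data_seeds):
        dataset = simulate_dataset(config, model, int(ds_seed))
        path = outdir / f"{stem}_{i}.txt"
        write_mdr(dataset, path)
        paths.append(path)
    sidecar = {
        "config": asdict(config),
        "penetrance_table": model.table.tolist(),
        "model_seed": model_seed,
        "dataset_seeds": [int(s) for s in data_seeds],
        "functional_pair": list(FUNCTIONAL_PAIR),
    }
    (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return paths
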