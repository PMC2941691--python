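"""Synthetic experiments with known ground truth.

The generator emulates a replicated factorial microarray experiment
after RMA-style preprocessing: per-feature baseline log2 intensities
drawn once per experiment, additive condition-specific shifts ("spikes")
on selected features, and i.i.d. Gaussian replicate noise on log2 scale.
Defaults — 3 replicates, ~N(8, 1.5²) baselines, σ = 0.25 log2 units of
replicate noise, 2-fold spike shifts — mirror a clean two-color-free
Affymetrix experiment of moderate quality.

Ground truth (which feature is shifted by how much in which T/C) is
written beside the fixture so downstream checks never re-derive truth
from the pipeline under test.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import Design, FactorDecl, Sample, SampleSet, write_design
from .matrix import ExpressionMatrix
from .tc import enumerate_tcs


@dataclass(frozen=True)
class Spike:
    """An additive log2 shift applied to one feature in matching sample sets.

    ``where`` maps factor → level; a sample set receives the shift when
    its profile matches every entry.  For a T/C contrasting ``where``'s
    factor level against the control level, the induced true LOG2R is
    ``delta``.
    """

    feature: str
    where: dict[str, str]
    delta: float

    def applies(self, profile: dict[str, str]) -> bool:
        return all(profile.get(f) == lvl for f, lvl in self.where.items())


def _freeze(d: dict[str, str]) -> tuple:
    return tuple(sorted(d.items()))


@dataclass(frozen=True)
class SyntheticDesignSpec:
    """Parameters of one synthetic factorial experiment."""

    factors: tuple[FactorDecl, ...]
    n_features: int = 500
    replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    spikes: tuple[Spike, ...] = ()
    seed: int = 0
    experiment_id: str = "synth"
    feature_prefix: str = "g"

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.replicates < 2:
            raise ValueError("sample sets must be replicated (>=2)")
        names = {f"{self.feature_prefix}{i:05d}" for i in range(self.n_features)}
        for s in self.spikes:
            if s.feature not in names:
                raise ValueError(f"spiked feature {s.feature!r} does not exist")

    def feature_ids(self) -> list[str]:
        return [f"{self.feature_prefix}{i:05d}" for i in range(self.n_features)]


@dataclass
class SyntheticExperiment:
    matrix: ExpressionMatrix
    design: Design
    truth: pd.DataFrame  # columns: tc_id, feature_id, true_log2r


def _sanitize(level: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in level)


def _factorial_sample_sets(spec: SyntheticDesignSpec) -> list[tuple[str, dict[str, str]]]:
    combos: list[dict[str, str]] = [{}]
    for f in spec.factors:
        combos = [{**c, f.name: lvl} for c in combos for lvl in f.levels]
    out = []
    for c in combos:
        name = "_".join(_sanitize(c[f.name]) for f in spec.factors) or "all"
        out.append((name, c))
    return out


def generate_experiment(spec: SyntheticDesignSpec, outdir: str | None = None) -> SyntheticExperiment:
    """Generate matrix + design + truth table for one factorial experiment.

    Replicate chip values are ``baseline_f + Σ applicable spike shifts +
    N(0, noise_sd²)`` on log2 scale.  The truth table lists the true
    LOG2R of every (enumerated T/C, spiked feature) pair.  When
    ``outdir`` is given, writes ``matrix.tsv``, ``design.yaml`` and
    ``truth.tsv`` there (byte-identical across runs with the same spec).
    """
    rng = np.random.default_rng(spec.seed)
    features = spec.feature_ids()
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_features)

    set_defs = _factorial_sample_sets(spec)
    shift = {name: np.zeros(spec.n_features) for name, _ in set_defs}
    fidx = {f: i for i, f in enumerate(features)}
    for name, profile in set_defs:
        for s in spec.spikes:
            if s.applies(profile):
                shift[name][fidx[s.feature]] += s.delta

    columns: dict[str, np.ndarray] = {}
    sample_sets = []
    for name, profile in set_defs:
        members = []
        for r in range(1, spec.replicates + 1):
            chip = f"{name}_r{r}"
            columns[chip] = baseline + shift[name] + rng.normal(0.0, spec.noise_sd, size=spec.n_features)
            members.append(Sample(sample_id=chip, chip_column=chip))
        sample_sets.append(SampleSet(name=name, members=members, profile=dict(profile)))

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=features), scale="log2")
    factors = {f.name: f for f in spec.factors}
    design = Design(
        factors=factors,
        sample_sets=sample_sets,
        experiment_id=spec.experiment_id,
        title=f"Synthetic factorial experiment {spec.experiment_id}",
        description=(
            f"Synthetic data: {spec.n_features} features, {spec.replicates} replicates, "
            f"noise sd {spec.noise_sd} (log2)."
        ),
    )

    tcs = enumerate_tcs(sample_sets, factors)
    rows = []
    spiked = sorted({s.feature for s in spec.spikes})
    shift_by_name = shift
    for tc in tcs:
        dt = shift_by_name[tc.treatment.name]
        dc = shift_by_name[tc.control.name]
        for f in spiked:
            true = dt[fidx[f]] - dc[fidx[f]]
            rows.append({"tc_id": tc.tc_id, "feature_id": f, "true_log2r": true})
    truth = pd.DataFrame(rows, columns=["tc_id", "feature_id", "true_log2r"])

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        matrix.write_tsv(os.path.join(outdir, "matrix.tsv"))
        write_design(design, os.path.join(outdir, "design.yaml"))
        truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False, float_format="%.10g")
    return SyntheticExperiment(matrix=matrix, design=design, truth=truth)


def spike_relations(
    spec: SyntheticDesignSpec,
    pairs: list[tuple[str, str, int]],
    scale: float = 1.0,
) -> SyntheticDesignSpec:
    """Copy each (gene_a → gene_b) spike pattern with sign ``±1`` and ``scale``.

    gene_b inherits gene_a's shifts across all conditions (scaled, and
    negated for sign −1), so its true regulation set coincides with
    gene_a's and their LOG2Rs correlate with the requested sign.
    """
    extra = []
    by_feature: dict[str, list[Spike]] = {}
    for s in spec.spikes:
        by_feature.setdefault(s.feature, []).append(s)
    for gene_a, gene_b, sign in pairs:
        if sign not in (1, -1):
            raise ValueError("target CC sign must be +1 or -1")
        if gene_a not in by_feature:
            raise ValueError(f"gene {gene_a!r} has no spikes to copy")
        for s in by_feature[gene_a]:
            extra.append(Spike(feature=gene_b, where=dict(s.where), delta=sign * scale * s.delta))
    return replace(spec, spikes=tuple(spec.spikes) + tuple(extra))


def ice1_like_spec(seed: int = 0, n_features: int = 200, **kwargs) -> SyntheticDesignSpec:
    """A 2-genotype × 4-cold-duration factorial (the classic 8-set layout
    whose single-differing-factor enumeration yields 10 T/Cs)."""
    factors = (
        FactorDecl(name="genotype", levels=("wild type", "ice1"), control_level="wild type"),
        FactorDecl(name="cold", levels=("none", "3 hr", "6 hr", "24 hr"), control_level="none"),
    )
    return SyntheticDesignSpec(factors=factors, n_features=n_features, seed=seed, **kwargs)
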