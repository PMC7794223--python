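"""Synthetic bulk and single-cell cohorts with planted telomerase structure.

Bulk cohorts are log-normal: every gene has a baseline log-expression, and the
planted signature genes (one anchor constituent, one RNA-subunit constituent,
and a marker block) receive an additive log-scale shift proportional to
``effect_size`` times a latent per-sample activity in [0, 1].  The same
latent activity both upregulates the planted genes in the high-activity group
and, because their idiosyncratic noise is kept small, makes them mutually
co-expressed (anchored on the constituent gene) — the minimal structure under
which the derivation pipeline is identifiable.  One RNG stream per cohort
makes cohorts bit-reproducible given (seed, params).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from extendscore.exprio import ExpressionMatrix, ValidationError
from extendscore.scoring import GeneSignature

GROUP_TELOMERASE = "telomerase-positive"
GROUP_ALT = "ALT-like"
GROUP_NO_TMM = "no-TMM"

#: per-group latent activity ranges (uniform); telomerase-positive is
#: constructed strictly higher on average than ALT-like and no-TMM.  The wide
#: telomerase-positive range is what makes the planted genes mutually
#: co-expressed within that group: activity is the shared latent factor.
ACTIVITY_RANGES = {
    GROUP_TELOMERASE: (0.40, 1.00),
    GROUP_ALT: (0.00, 0.20),
    GROUP_NO_TMM: (0.00, 0.10),
}

PHASE_ACTIVITY_RANGES = {
    "G1-S": (0.75, 0.95),
    "G2-M": (0.50, 0.70),
    "non-cycling": (0.05, 0.25),
}


@dataclass
class SyntheticCohort:
    expr: ExpressionMatrix
    activity: np.ndarray
    group: np.ndarray
    planted_signature: GeneSignature
    seed: int
    params: dict = field(default_factory=dict)


def _group_sizes(n: int, fractions) -> list[int]:
    fr = np.asarray(fractions, dtype=float)
    if fr.ndim != 1 or np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
        raise ValidationError("group fractions must be non-negative and sum to 1")
    bounds = np.round(np.cumsum(fr) * n).astype(int)
    sizes = np.diff(np.concatenate([[0], bounds]))
    if sizes.sum() != n:
        sizes[-1] += n - sizes.sum()
    return [int(s) for s in sizes]


def _signature_gene_names(n_markers: int) -> tuple[tuple[str, str], list[str]]:
    markers = [f"MK{i + 1:02d}" for i in range(n_markers)]
    return ("TERT", "TERC"), markers


def simulate_bulk(
    n_genes: int = 200,
    n_samples: int = 100,
    n_markers: int = 11,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    group_fractions=(0.4, 0.4, 0.2),
    seed: int = 0,
    sig_noise_frac: float = 0.2,
    baseline_range: tuple[float, float] = (1.5, 6.5),
) -> SyntheticCohort:
    """Two-group-plus-control bulk cohort with a planted co-expressed module.

    ``effect_size`` is the natural-log expression shift per unit activity for
    the 2 + ``n_markers`` planted signature genes.  Those genes are tightly
    co-regulated by the latent activity: their idiosyncratic noise is
    ``sig_noise_frac * noise_sd``, so within the telomerase-positive group the
    shared activity variation dominates and anchors mutual Pearson
    co-expression on the constituent gene.
    """
    if n_markers + 2 >= n_genes:
        raise ValidationError("n_markers + 2 must be < n_genes")
    if len(tuple(group_fractions)) != 3:
        raise ValidationError("group_fractions must give 3 proportions "
                              f"({GROUP_TELOMERASE}, {GROUP_ALT}, {GROUP_NO_TMM})")
    if not 0.0 < sig_noise_frac <= 1.0:
        raise ValidationError("sig_noise_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)

    sizes = _group_sizes(n_samples, group_fractions)
    groups = [GROUP_TELOMERASE, GROUP_ALT, GROUP_NO_TMM]
    group = np.repeat(groups, sizes)
    activity = np.concatenate(
        [rng.uniform(*ACTIVITY_RANGES[g], size=s) for g, s in zip(groups, sizes)]
    )

    constituent, markers = _signature_gene_names(n_markers)
    n_background = n_genes - n_markers - 2
    gene_ids = list(constituent) + markers + [f"BG{i + 1:04d}" for i in range(n_background)]
    sig_rows = np.arange(n_markers + 2)

    mu = rng.uniform(*baseline_range, size=n_genes)
    z = mu[:, None] + noise_sd * rng.standard_normal((n_genes, n_samples))
    z[sig_rows] = (
        mu[sig_rows, None]
        + effect_size * activity[None, :]
        + sig_noise_frac * noise_sd * rng.standard_normal((sig_rows.size, n_samples))
    )
    values = np.exp(z)

    expr = ExpressionMatrix(
        gene_ids, [f"S{i + 1:04d}" for i in range(n_samples)], values
    )
    params = {
        "kind": "bulk",
        "n_genes": n_genes,
        "n_samples": n_samples,
        "n_markers": n_markers,
        "effect_size": effect_size,
        "noise_sd": noise_sd,
        "group_fractions": list(group_fractions),
        "sig_noise_frac": sig_noise_frac,
        "baseline_range": list(baseline_range),
        "seed": seed,
    }
    return SyntheticCohort(
        expr=expr,
        activity=activity,
        group=np.asarray(group, dtype=object),
        planted_signature=GeneSignature(constituent, markers, name="planted-bulk"),
        seed=seed,
        params=params,
    )


def simulate_single_cell(
    n_genes: int = 200,
    n_cells: int = 300,
    dropout_rate: float = 0.4,
    constituent_dropout: bool = True,
    phase_fractions=(0.25, 0.25, 0.5),
    seed: int = 0,
    n_markers: int = 11,
    n_phase_markers: int = 15,
    effect_size: float = 2.0,
    phase_marker_rate: float = 30.0,
) -> SyntheticCohort:
    """Sparse count cohort with planted cycling phases and Bernoulli dropout.

    Cells belong to G1-S / G2-M / non-cycling populations; phase-marker genes
    take Poisson rate ``phase_marker_rate`` in their phase and 0.2 elsewhere.
    Cycling cells carry higher latent activity (G1-S highest), which elevates
    the planted signature marker genes.  With ``constituent_dropout`` the
    TERT/TERC rows are zeroed everywhere, emulating assays that cannot detect
    either constituent transcript.
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValidationError("dropout_rate must be in [0, 1)")
    if len(tuple(phase_fractions)) != 3:
        raise ValidationError("phase_fractions must give 3 proportions (G1-S, G2-M, non-cycling)")
    n_special = 2 + n_markers + 2 * n_phase_markers
    if n_special >= n_genes:
        raise ValidationError(f"n_genes must exceed {n_special} (signature + phase markers)")
    rng = np.random.default_rng(seed)

    phases = ["G1-S", "G2-M", "non-cycling"]
    sizes = _group_sizes(n_cells, phase_fractions)
    phase = np.repeat(phases, sizes)
    activity = np.concatenate(
        [rng.uniform(*PHASE_ACTIVITY_RANGES[p], size=s) for p, s in zip(phases, sizes)]
    )

    constituent, markers = _signature_gene_names(n_markers)
    g1s_genes = [f"G1S{i + 1:02d}" for i in range(n_phase_markers)]
    g2m_genes = [f"G2M{i + 1:02d}" for i in range(n_phase_markers)]
    n_background = n_genes - n_special
    gene_ids = (
        list(constituent)
        + markers
        + g1s_genes
        + g2m_genes
        + [f"BG{i + 1:04d}" for i in range(n_background)]
    )

    lam = np.exp(rng.uniform(0.5, 3.0, size=n_genes))[:, None] * np.ones((1, n_cells))
    sig_rows = np.arange(2 + n_markers)
    lam[sig_rows] = lam[sig_rows] * np.exp(effect_size * activity[None, :])
    g1s_rows = np.arange(2 + n_markers, 2 + n_markers + n_phase_markers)
    g2m_rows = g1s_rows + n_phase_markers
    lam[g1s_rows] = np.where(phase[None, :] == "G1-S", phase_marker_rate, 0.2)
    lam[g2m_rows] = np.where(phase[None, :] == "G2-M", phase_marker_rate, 0.2)

    counts = rng.poisson(lam).astype(float)
    keep = rng.random((n_genes, n_cells)) >= dropout_rate
    counts *= keep
    if constituent_dropout:
        counts[:2] = 0.0

    expr = ExpressionMatrix(gene_ids, [f"C{i + 1:04d}" for i in range(n_cells)], counts)
    params = {
        "kind": "single-cell",
        "n_genes": n_genes,
        "n_cells": n_cells,
        "dropout_rate": dropout_rate,
        "constituent_dropout": constituent_dropout,
        "phase_fractions": list(phase_fractions),
        "n_markers": n_markers,
        "n_phase_markers": n_phase_markers,
        "effect_size": effect_size,
        "phase_marker_rate": phase_marker_rate,
        "seed": seed,
        "g1s_genes": g1s_genes,
        "g2m_genes": g2m_genes,
    }
    return SyntheticCohort(
        expr=expr,
        activity=activity,
        group=np.asarray(phase, dtype=object),
        planted_signature=GeneSignature(constituent, markers, name="planted-sc"),
        seed=seed,
        params=params,
    )
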