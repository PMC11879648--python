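"""Synthetic cluster generation and benchmark of summarization methods.

The generator emulates a single-mixture TMT group-comparison experiment on
one cluster of proteins with pairwise shared peptides. Protein-level channel
abundances follow the group-comparison linear model (condition means plus
i.i.d. channel-level error); feature-level log2 intensities follow the
weighted summarization model with known generating weights and i.i.d. normal
feature noise. The benchmark summarizes each simulated cluster with the
weighted, unique-only and all-peptides methods, tests every protein against
the reference condition (p < 0.05, unadjusted), and reports mean-squared
error and bias of the log2 fold-change estimates plus sensitivity and
specificity of detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import HuberConfig, summarize_features
from .stats import test_all_contrasts

logger = logging.getLogger(__name__)

_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Generating conditions for the simulated cluster.

    Defaults: a cluster of five proteins, two unique peptides per protein
    and five shared peptides per protein pair, five conditions with two
    biological replicates each (one mixture), feature-level noise sd 0.2 and
    channel-level (biological) error sd 0.2. Three of the five proteins are
    differentially abundant, with per-condition log2 fold changes versus the
    reference of magnitude 0.5/1.0/1.5/2.0 and alternating sign across the
    changed proteins. Shared peptides are generated wholly from one protein
    of their pair (alternating); ``shared_weighting='mixed'`` draws a random
    convex combination instead.
    """

    n_proteins: int = 5
    n_unique_per_protein: int = 2
    n_shared_per_pair: int = 5
    n_conditions: int = 5
    n_bioreps_per_condition: int = 2
    true_log2fc: np.ndarray | None = None  # K x G, reference column 0 all zero
    n_differential: int = 3
    effect_magnitudes: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    noise_sd: float = 0.2
    channel_sd: float = 0.2
    feature_sd: float = 0.5
    baseline_mean: float = 16.0
    baseline_sd: float = 1.0
    shared_weighting: str = "alternating"
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_unique_per_protein", "n_conditions",
                     "n_bioreps_per_condition", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.channel_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")

    def resolved_log2fc(self) -> np.ndarray:
        """The K x G matrix of true log2 fold changes vs the reference."""
        if self.true_log2fc is not None:
            fc = np.asarray(self.true_log2fc, float)
            if fc.shape != (self.n_proteins, self.n_conditions):
                raise ValueError("true_log2fc must be n_proteins x n_conditions")
            return fc
        fc = np.zeros((self.n_proteins, self.n_conditions))
        mags = list(self.effect_magnitudes)
        for j in range(min(self.n_differential, self.n_proteins)):
            sign = 1.0 if j % 2 == 0 else -1.0
            for g in range(1, self.n_conditions):
                fc[j, g] = sign * mags[(g - 1) % len(mags)]
        return fc


@dataclass
class ClusterTruth:
    """Generating parameters of one simulated cluster."""

    proteins: list[str]
    conditions: list[str]
    reference: str
    true_log2fc: np.ndarray  # K x G
    weights: np.ndarray  # F x K
    feature_ids: list[str]
    protein_channel: np.ndarray  # K x C true log2 abundances
    feature_effects: np.ndarray


def _random_peptide(rng: np.random.Generator, length: int = 10) -> str:
    return "".join(rng.choice(_AMINO, size=length))


def simulate_cluster(
    config: SimulationConfig, seed: int | list[int] | None = None
) -> tuple[pd.DataFrame, ClusterTruth]:
    """Generate one cluster's feature table and its ground truth.

    Deterministic given the seed: the same seed yields an identical table.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    K, G, B = config.n_proteins, config.n_conditions, config.n_bioreps_per_condition
    C = G * B
    fc = config.resolved_log2fc()
    proteins = [f"Prot{k + 1}" for k in range(K)]
    conditions = [f"cond{g + 1}" for g in range(G)]
    channel_condition = np.repeat(np.arange(G), B)
    channel_biorep = np.tile(np.arange(1, B + 1), G)
    channels = [f"ch{c + 1:02d}" for c in range(C)]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=K)
    T = (
        baseline[:, None]
        + fc[:, channel_condition]
        + rng.normal(0.0, config.channel_sd, size=(K, C))
    )

    memberships: list[tuple[int, ...]] = []
    true_w: list[np.ndarray] = []
    for k in range(K):
        for _ in range(config.n_unique_per_protein):
            w = np.zeros(K)
            w[k] = 1.0
            memberships.append((k,))
            true_w.append(w)
    pair_toggle = 0
    for i in range(K):
        for j in range(i + 1, K):
            for s in range(config.n_shared_per_pair):
                w = np.zeros(K)
                if config.shared_weighting == "mixed":
                    u = rng.uniform()
                    w[i], w[j] = u, 1.0 - u
                else:  # alternating whole assignment within the pair
                    owner = (i, j)[(s + pair_toggle) % 2]
                    w[owner] = 1.0
                memberships.append((i, j))
                true_w.append(w)
            pair_toggle += 1
    W = np.vstack(true_w) if true_w else np.zeros((0, K))
    F = W.shape[0]

    feature_effects = rng.normal(0.0, config.feature_sd, size=F)
    # identification convention of the fitted model: weighted feature
    # effects are centered within every protein (implies the global sum-to-
    # zero), so the recorded protein profiles are the identified truth
    delta = np.linalg.pinv(W.T @ W) @ (W.T @ feature_effects)
    feature_effects = feature_effects - W @ delta
    X = (
        feature_effects[:, None]
        + W @ T
        + rng.normal(0.0, config.noise_sd, size=(F, C))
    )

    peptides = []
    seen: set[str] = set()
    for _ in range(F):
        pep = _random_peptide(rng)
        while pep in seen:
            pep = _random_peptide(rng)
        seen.add(pep)
        peptides.append(pep)
    feature_ids = [f"{pep}_2" for pep in peptides]

    rows = []
    for f in range(F):
        label = ";".join(sorted(proteins[k] for k in memberships[f]))
        for c in range(C):
            rows.append(
                {
                    "protein": label,
                    "peptide": peptides[f],
                    "feature_id": feature_ids[f],
                    "mixture": "1",
                    "channel": channels[c],
                    "condition": conditions[channel_condition[c]],
                    "bio_replicate": f"{conditions[channel_condition[c]]}_r{channel_biorep[c]}",
                    "log2_intensity": X[f, c],
                }
            )
    table = pd.DataFrame(rows)
    truth = ClusterTruth(
        proteins=proteins,
        conditions=conditions,
        reference=conditions[0],
        true_log2fc=fc,
        weights=W,
        feature_ids=feature_ids,
        protein_channel=T,
        feature_effects=feature_effects,
    )
    return table, truth


def reference_contrasts(truth: ClusterTruth) -> pd.DataFrame:
    """Contrast matrix: each non-reference condition versus the reference."""
    rows = {}
    for cond in truth.conditions[1:]:
        coef = {c: 0.0 for c in truth.conditions}
        coef[cond] = 1.0
        coef[truth.reference] = -1.0
        rows[f"{cond} vs {truth.reference}"] = coef
    return pd.DataFrame(rows).T


@dataclass
class BenchmarkResult:
    """Aggregated benchmark output.

    ``estimates`` holds one row per (replicate, method, protein, contrast)
    with the estimated and true log2 fold change and the unadjusted p-value;
    ``metrics`` aggregates mse/bias/sensitivity/specificity per method.
    """

    estimates: pd.DataFrame
    metrics: pd.DataFrame
    failures: dict[str, int] = field(default_factory=dict)


def run_benchmark(
    config: SimulationConfig,
    methods: tuple[str, ...] = ("weighted", "unique", "all"),
    fit_config: HuberConfig | None = None,
    alpha: float = 0.05,
) -> BenchmarkResult:
    """Simulate, summarize by each method, and test against the reference.

    Detection uses unadjusted p-values at the given cutoff. Sensitivity is
    the fraction of truly changed (protein, contrast) pairs detected;
    specificity the fraction of truly null pairs not detected. All methods
    see identical replicate data (per-replicate substreams of the master
    seed). A method failing on a replicate is excluded for that method and
    counted in ``failures``.
    """
    fit_config = fit_config or HuberConfig()
    records: list[dict] = []
    failures = {m: 0 for m in methods}
    for rep in range(config.n_replicates):
        table, truth = simulate_cluster(config, seed=[config.seed, rep])
        contrasts = reference_contrasts(truth)
        true_fc = {
            (truth.proteins[k], f"{cond} vs {truth.reference}"): truth.true_log2fc[k, g]
            for k in range(len(truth.proteins))
            for g, cond in enumerate(truth.conditions)
            if g > 0
        }
        for method in methods:
            try:
                summaries, _, _ = summarize_features(table, fit_config, method=method)
                res = test_all_contrasts(summaries, contrasts)
            except Exception:
                logger.exception("method %s failed on replicate %d", method, rep)
                failures[method] += 1
                continue
            for _, r in res.iterrows():
                key = (str(r["protein"]), str(r["contrast"]))
                if key not in true_fc:
                    continue
                records.append(
                    {
                        "replicate": rep,
                        "method": method,
                        "protein": key[0],
                        "contrast": key[1],
                        "true_log2fc": true_fc[key],
                        "log2fc": float(r["log2fc"]),
                        "p_value": float(r["p_value"]),
                    }
                )
    estimates = pd.DataFrame(records)
    metrics = summarize_benchmark(estimates, alpha=alpha)
    return BenchmarkResult(estimates=estimates, metrics=metrics, failures=failures)


def summarize_benchmark(estimates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-method mse, bias, sensitivity and specificity."""
    rows = []
    for method, sub in estimates.groupby("method", sort=True):
        err = sub["log2fc"] - sub["true_log2fc"]
        changed = sub["true_log2fc"] != 0
        null = ~changed
        detected = sub["p_value"] < alpha
        rows.append(
            {
                "method": method,
                "mse": float((err ** 2).mean()),
                "bias": float(err.mean()),
                "sensitivity": float(detected[changed].mean()) if changed.any() else np.nan,
                "specificity": float((~detected[null]).mean()) if null.any() else np.nan,
                "n_tests": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# resampling of unique peptides
# --------------------------------------------------------------------------

def _feature_profiles(features: pd.DataFrame) -> pd.DataFrame:
    return features.pivot_table(
        index="feature_id", columns=["mixture", "channel"],
        values="log2_intensity", aggfunc="mean",
    )


def noisy_pool(
    features: pd.DataFrame, protein: str, pool_size: int = 3
) -> list[str]:
    """Unique peptides of ``protein`` with the lowest average Pearson
    correlation to the other peptides matching that protein."""
    from .graph import membership_from_table

    members = membership_from_table(features)
    of_protein = [f for f, mem in members.items() if protein in mem]
    unique = [f for f in of_protein if members[f] == frozenset({protein})]
    if len(unique) <= pool_size:
        return sorted(unique)
    prof = _feature_profiles(features).loc[of_protein]
    corr = prof.T.corr()
    avg = {}
    for f in unique:
        others = [g for g in of_protein if g != f]
        avg[f] = float(corr.loc[f, others].mean())
    ranked = sorted(unique, key=lambda f: (avg[f], f))
    return ranked[:pool_size]


def resample_unique(
    features: pd.DataFrame,
    n_unique: int,
    include_noisy: bool = False,
    seed: int | list[int] = 0,
) -> pd.DataFrame:
    """Randomly keep ``n_unique`` unique peptides per protein, all shared.

    With ``include_noisy``, one of the retained unique peptides is drawn
    from the pool of the three unique peptides least correlated with the
    protein's other peptides. Deterministic given the seed. A protein with
    fewer unique peptides than requested raises an error naming it.
    """
    from .graph import membership_from_table

    rng = np.random.default_rng(seed)
    members = membership_from_table(features)
    proteins = sorted({p for mem in members.values() for p in mem})
    keep: set[str] = {f for f, mem in members.items() if len(mem) > 1}
    for protein in proteins:
        unique = sorted(
            f for f, mem in members.items() if mem == frozenset({protein})
        )
        if len(unique) < n_unique:
            raise ValueError(
                f"protein {protein} has {len(unique)} unique features, "
                f"fewer than the requested {n_unique}"
            )
        if include_noisy:
            pool = noisy_pool(features, protein)
            noisy = str(rng.choice(pool))
            rest = [f for f in unique if f != noisy]
            chosen = {noisy} | set(
                rng.choice(rest, size=n_unique - 1, replace=False)
            ) if n_unique > 1 else {noisy}
        else:
            chosen = set(rng.choice(unique, size=n_unique, replace=False))
        keep |= chosen
    return features[features["feature_id"].isin(keep)].reset_index(drop=True)


def mse_against_reference(
    estimates: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Per-method MSE of log2 fold changes against reference estimates.

    ``estimates`` has columns method, protein, contrast, log2fc (one row per
    resampling instance and test); ``reference`` has protein, contrast,
    log2fc. Rows without a matching reference or with a missing estimate are
    excluded and counted.
    """
    if estimates.empty:
        raise ValueError("no estimates provided")
    ref = reference.set_index(["protein", "contrast"])["log2fc"]
    rows = []
    for method, sub in estimates.groupby("method", sort=True):
        idx = pd.MultiIndex.from_frame(sub[["protein", "contrast"]])
        matched = idx.isin(ref.index)
        dev = sub.loc[matched, "log2fc"].to_numpy(float) - ref.loc[idx[matched]].to_numpy(float)
        ok = np.isfinite(dev)
        rows.append(
            {
                "method": method,
                "mse": float(np.mean(dev[ok] ** 2)) if ok.any() else np.nan,
                "n_used": int(ok.sum()),
                "n_missing": int(len(sub) - ok.sum()),
            }
        )
    return pd.DataFrame(rows)


def null_config(base: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A copy of the configuration with all true log2 fold changes zero."""
    base = base or SimulationConfig()
    cfg = replace(base, **overrides)
    return replace(
        cfg, true_log2fc=np.zeros((cfg.n_proteins, cfg.n_conditions))
    )
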