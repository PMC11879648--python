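import numpy as np
import pandas as pd
import pytest

from pepshare import core, sim


def make_feature_table(membership: dict[str, list[str]], values: dict[str, list[float]],
                       conditions: list[str] | None = None,
                       bioreps: list[str] | None = None,
                       mixture: str = "1") -> pd.DataFrame:
    """Build a canonical feature table from per-feature membership and
    per-feature channel values (NaN allowed)."""
    n_ch = len(next(iter(values.values())))
    channels = [f"ch{c + 1:02d}" for c in range(n_ch)]
    conditions = conditions or ["g1"] * n_ch
    bioreps = bioreps or [f"b{c + 1}" for c in range(n_ch)]
    rows = []
    for fid, prots in membership.items():
        for c, channel in enumerate(channels):
            rows.append(
                {
                    "protein": ";".join(sorted(prots)),
                    "peptide": fid.split("_")[0],
                    "feature_id": fid,
                    "mixture": mixture,
                    "channel": channel,
                    "condition": conditions[c],
                    "bio_replicate": bioreps[c],
                    "log2_intensity": values[fid][c],
                }
            )
    return pd.DataFrame(rows)


#: peptide-protein topology of the worked two-cluster example: proteins A
#: and B share peptides 3 and 4; C's peptides 7 and 8 are all shared with D,
#: and only D has a unique peptide (9).
TWO_CLUSTER_MEMBERSHIP = {
    "p1_2": ["A"], "p2_2": ["A"],
    "p3_2": ["A", "B"], "p4_2": ["A", "B"],
    "p5_2": ["B"], "p6_2": ["B"],
    "p7_2": ["C", "D"], "p8_2": ["C", "D"],
    "p9_2": ["D"],
}


@pytest.fixture
def two_cluster_features() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    values = {fid: list(rng.normal(15, 1, 4)) for fid in TWO_CLUSTER_MEMBERSHIP}
    return make_feature_table(TWO_CLUSTER_MEMBERSHIP, values)


@pytest.fixture(scope="session")
def benchmark_20() -> sim.BenchmarkResult:
    """Shared 20-replicate benchmark under the default generating
    conditions; used by the directional bias/variance and
    sensitivity/specificity checks."""
    return sim.run_benchmark(sim.SimulationConfig(n_replicates=20, seed=0))


def two_protein_cluster(noise_sd: float, channel_sd: float, seed,
                        n_shared: int = 4) -> tuple[core.ClusterData, sim.ClusterTruth]:
    cfg = sim.SimulationConfig(
        n_proteins=2, n_shared_per_pair=n_shared,
        noise_sd=noise_sd, channel_sd=channel_sd,
    )
    table, truth = sim.simulate_cluster(cfg, seed=seed)
    from pepshare.graph import prepare_clusters

    cluster = prepare_clusters(table)[0]
    return core.cluster_data(table, cluster, "1"), truth


def align_weights(fit: core.ClusterFit, truth: sim.ClusterTruth) -> np.ndarray:
    """Estimated minus true weights, aligned by feature id and protein."""
    est = pd.DataFrame(fit.weights, index=fit.feature_ids, columns=fit.proteins)
    true = pd.DataFrame(truth.weights, index=truth.feature_ids, columns=truth.proteins)
    est = est.reindex(index=true.index, columns=true.columns).fillna(0.0)
    return (est - true).to_numpy()
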