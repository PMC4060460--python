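import numpy as np
import pandas as pd
import pytest

from fuzzyrules import (
    CLASSES,
    CenterSpec,
    CohortSpec,
    ExpressionDataset,
    MarkerSpec,
    generate_cohorts,
    preprocess,
)


def strong_marker_spec(delta=1.2, sigma=0.3, n_markers=5):
    """Markers at delta = 4*sigma for every (class, direction)."""
    return tuple(
        MarkerSpec(conclusion=c, direction=d, n_markers=n_markers, delta=delta, sigma=sigma)
        for c in CLASSES
        for d in ("high", "low")
    )


def make_cohort_spec(seed=7, n_genes=400, **kwargs):
    kwargs.setdefault("marker_spec", strong_marker_spec())
    return CohortSpec(seed=seed, n_genes=n_genes, **kwargs)


def toy_dataset(signals, present=None, labels=None, center="toy"):
    """Small hand-specified dataset; signals is a genes x samples 2-D list."""
    signals = np.asarray(signals, dtype=float)
    g, n = signals.shape
    genes = [f"g{i+1}" for i in range(g)]
    samples = [f"s{j+1}" for j in range(n)]
    if present is None:
        present = np.ones_like(signals, dtype=bool)
    if labels is None:
        labels = (list(CLASSES) * n)[:n]
    return ExpressionDataset(
        signals=pd.DataFrame(signals, index=genes, columns=samples),
        present=pd.DataFrame(np.asarray(present, dtype=bool), index=genes, columns=samples),
        labels=pd.Series(labels, index=samples),
        center=center,
    )


def random_prune_instance(rng):
    """Small random instance for pruning-oracle checks: <= 15 samples,
    a few genes with weak planted class signal, rule lists capped at 6.
    Returns (values, labels, models, system) or None if no rules arise."""
    from fuzzyrules import GeneClusterModels, enumerate_rules

    n = int(rng.integers(9, 16))
    g = int(rng.integers(6, 12))
    values = pd.DataFrame(
        rng.normal(0, 1, size=(g, n)),
        index=[f"g{i}" for i in range(g)],
        columns=[f"s{j}" for j in range(n)],
    )
    labels = pd.Series(rng.choice(CLASSES, size=n), index=values.columns)
    # weak, noisy class signal in a random subset of genes
    for gi in rng.choice(g, size=3, replace=False):
        cls = rng.choice(CLASSES)
        values.iloc[gi] += np.where(labels == cls, float(rng.uniform(1.0, 2.5)), 0.0)
    models = GeneClusterModels.fit(values)
    system = enumerate_rules(values, labels, models,
                             alpha=float(rng.choice([0.5, 0.6, 0.7, 0.8])))
    system.rules = {c: lst[:6] for c, lst in system.rules.items()}
    if all(len(v) == 0 for v in system.rules.values()):
        return None
    return values, labels, models, system


@pytest.fixture(scope="session")
def table2_cohort():
    """Three preprocessed centers with the study-sized class mix and
    well-separated planted markers (delta = 4 sigma)."""
    datasets, truth = generate_cohorts(make_cohort_spec())
    return [preprocess(d) for d in datasets], truth


@pytest.fixture(scope="session")
def small_trained(table2_cohort):
    """Classifier trained on the first (largest) center."""
    from fuzzyrules import fit_study_group

    pp, truth = table2_cohort
    return fit_study_group(pp[0]), pp, truth
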