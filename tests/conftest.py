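"""Shared fixtures: small simulated cohorts and synthetic feature tables.

Cohort fixtures are session-scoped because simulation plus feature
extraction dominates suite runtime; tests must not mutate them.
"""

import numpy as np
import pandas as pd
import pytest

from szeeg import (
    BAND_NAMES,
    CohortConfig,
    EffectSpec,
    extract_features,
    simulate_cohort,
)
from szeeg.features import feature_keys
from szeeg.synthetic import CouplingEdge


def neutral_effects(**overrides) -> EffectSpec:
    """Neutral EffectSpec with selected fields overridden."""
    eff = EffectSpec.neutral()
    for k, v in overrides.items():
        setattr(eff, k, v)
    return eff


def simulate_table(
    effects: EffectSpec,
    families=("RP", "FuzEn", "PLI"),
    bands=None,
    n_per_group: int = 20,
    duration_s: float = 16.0,
    seed: int = 11,
    window_s: float = 4.0,
) -> pd.DataFrame:
    """Simulate a cohort and extract (a subset of) its features."""
    from szeeg.core import DEFAULT_BANDS

    config = CohortConfig(
        n_hc=n_per_group, n_scz=n_per_group, duration_s=duration_s,
        seed=seed, effects=effects,
    )
    recordings, _ = simulate_cohort(config)
    kwargs = {"window_length_s": window_s, "families": families}
    if bands is not None:
        kwargs["bands"] = tuple(
            b for b in DEFAULT_BANDS if b.name in bands
        )
    return extract_features(recordings, **kwargs)


def make_table(
    n_rows: int = 120,
    n_features: int = 10,
    n_informative: int = 0,
    effect: float = 2.0,
    seed: int = 0,
    windows_per_subject: int = 5,
) -> pd.DataFrame:
    """Gaussian-feature table with optional informative columns.

    Column names reuse the canonical feature keys so they parse as
    family/band/site; the first ``n_informative`` columns get a mean shift
    of ``effect`` in the SCZ rows.
    """
    rng = np.random.default_rng(seed)
    n_scz = n_rows // 2
    y = np.array([0] * (n_rows - n_scz) + [1] * n_scz)
    x = rng.normal(size=(n_rows, n_features))
    x[:, :n_informative] += effect * y[:, None]
    names = [k.name for k in feature_keys()][:n_features]
    table = pd.DataFrame(x, columns=names)
    table.insert(0, "subject_id",
                 [f"S{i // windows_per_subject:03d}" for i in range(n_rows)])
    table.insert(1, "group", np.where(y == 1, "SCZ", "HC"))
    table.insert(2, "window_index",
                 [i % windows_per_subject for i in range(n_rows)])
    return table


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort with the default planted effects (4+4 subjects, 16 s)."""
    config = CohortConfig(n_hc=4, n_scz=4, duration_s=16.0, seed=3)
    recordings, manifest = simulate_cohort(config)
    return config, recordings, manifest


@pytest.fixture(scope="session")
def alpha_shift_table():
    """RP features of a cohort whose only planted effect is a 0.5x alpha
    amplitude factor in SCZ (20 subjects per group)."""
    eff = neutral_effects(
        band_power_shift={**{b: 1.0 for b in BAND_NAMES}, "Alpha": 0.5}
    )
    return simulate_table(eff, families=("RP",), seed=21)


@pytest.fixture(scope="session")
def beta_coupling_tables():
    """Beta-band PLI features for a cohort with one planted coupled edge
    (F3-C3, coupling 0.0 in HC vs 0.6 in SCZ, lag pi/4)."""
    eff = neutral_effects(
        coupling_edges=(CouplingEdge("F3", "C3", "Beta", 0.0, 0.6, np.pi / 4),)
    )
    return simulate_table(eff, families=("PLI",), bands=("Beta",), seed=22)
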