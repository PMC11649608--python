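import numpy as np
import pandas as pd
import pytest

from dcews import AthleteSeries, CCPSeries, DCMatrix, ScaleSpec, SimConfig

UNIT = ScaleSpec("toy", 0.0, 1.0, "divide_by_100", 0.0, 1.0,
                 "psychological", "self_report")


def make_series(values: np.ndarray, factors=None, injuries=None,
                player_id="T01") -> AthleteSeries:
    """Wrap a T x V array of values in [0, 1] as an AthleteSeries."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    T, V = values.shape
    factors = factors or [f"f{i}" for i in range(V)]
    specs = {f: ScaleSpec(f, 0.0, 1.0, "divide_by_100", 0.0, 1.0,
                          "psychological", "self_report") for f in factors}
    df = pd.DataFrame(values, index=pd.RangeIndex(1, T + 1), columns=factors)
    mask = pd.Series(False, index=df.index)
    injuries = injuries or []
    for e in injuries:
        occ = [o for o in e.period if o in mask.index]
        mask.loc[occ] = True
    return AthleteSeries(player_id, df, specs, injuries, mask)


def make_dc(values, player_id="T01", window=7) -> DCMatrix:
    """Wrap an array (NaN allowed) as a DCMatrix without recomputation."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    T, V = values.shape
    cols = [f"f{i}" for i in range(V)]
    df = pd.DataFrame(values, index=pd.RangeIndex(1, T + 1), columns=cols)
    return DCMatrix(player_id, window, df, {c: 1.0 for c in cols})


def make_ccp(T: int, ccp_occasions, m: int = 7, player_id="T01") -> CCPSeries:
    """CCP series with flags exactly at *ccp_occasions*, defined from m."""
    idx = pd.RangeIndex(1, T + 1)
    count = pd.Series(np.where(idx >= m, 0.0, np.nan), index=idx)
    flags = pd.Series(False, index=idx)
    for occ in ccp_occasions:
        assert occ >= m, "CCPs only exist where DC is defined"
        flags.loc[occ] = True
        count.loc[occ] = 5.0
    return CCPSeries(player_id, count, flags, alpha=0.05, z_crit=1.645)


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(n_players=3, series_length_range=(60, 90), seed=11)
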