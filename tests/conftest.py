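"""Shared fixtures: a small simulated nucleus reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from meiostorm import nanofoci, synthdata
from meiostorm.locio import LocalizationTable


def small_params(**overrides) -> synthdata.GeneratorParams:
    """A compact nucleus (3 axes in a 12-um field) keeping the full-scale
    focus photophysics so all fixed thresholds behave as at full scale."""
    defaults = dict(
        n_axes=3,
        axis_length_range_um=(6.0, 8.0),
        field_um=12.0,
        n_fiducials=2,
    )
    defaults.update(overrides)
    return synthdata.GeneratorParams(**defaults)


@pytest.fixture(scope="session")
def sim_nucleus():
    params = small_params()
    # early zygotene: mostly unsynapsed axes with some synapsed pairs
    table, truth = synthdata.simulate_nucleus(
        params, seed=7, stage=synthdata.Stage.early_zygotene
    )
    return params, table, truth


@pytest.fixture(scope="session")
def segmented_sites(sim_nucleus):
    """Ground-truth-positioned ROIs segmented into nanofoci/configurations."""
    _, table, truth = sim_nucleus
    rois = [s.roi(nucleus_id=truth.nucleus_id) for s in truth.sites]
    segs = nanofoci.segment_rois(rois, table)
    configs = {}
    for site in truth.sites:
        nfs = segs[site.site_id]
        if nfs:
            cfg = nanofoci.classify_configuration(nfs, nucleus_id=truth.nucleus_id)
            nanofoci.assign_far_close(cfg)
            configs[site.site_id] = cfg
    return segs, configs


def make_table(xy, precision=15.0, channel="RAD51", nucleus_id="n0", frame=None,
               **table_kwargs) -> LocalizationTable:
    """Build a localization table from raw coordinates."""
    xy = np.asarray(xy, float).reshape(-1, 2)
    n = len(xy)
    prec = np.broadcast_to(np.asarray(precision, float), (n,))
    chan = np.broadcast_to(np.asarray(channel), (n,)).astype(object)
    frames = np.arange(n) if frame is None else np.broadcast_to(frame, (n,))
    df = pd.DataFrame(
        {"channel": chan, "frame": frames, "x_nm": xy[:, 0], "y_nm": xy[:, 1],
         "precision_nm": prec}
    )
    return LocalizationTable(nucleus_id, df, **table_kwargs)
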