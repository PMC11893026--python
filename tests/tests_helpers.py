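"""Small builders shared by a few tests (kept out of conftest fixtures)."""

import numpy as np

from cvpgrad import (GradientChainModel, SliceSet, build_scheme,
                     choose_prephasers, make_slice_select, make_trapezoid,
                     simulate_fid)


def constant_plateau_dataset():
    """Noiseless VP dataset with a long flat plateau; returns (data, G, r)."""
    g_plateau, r = 8.0, 10.0
    test = make_trapezoid(g_plateau, 100.0, 400.0, 1.0)
    ss, exc = make_slice_select(6.0, 100.0, 300.0, 1.0)
    amps = choose_prephasers(test, 2)
    sch = build_scheme("vp", test, amps, ss, exc, readout_duration=500.0)
    slices = SliceSet(np.array([r, -r]), 0.01)
    data = simulate_fid(sch, GradientChainModel(), slices, dwell=1.0,
                        intra_slice_points=1)
    return data, g_plateau, r
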