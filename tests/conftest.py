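"""Shared fixtures: small sequences, observer traces, one synthetic
subject, and a reduced virtual cohort with per-subject analysis maps.

Everything is generated programmatically at fixed seeds; the cohort is
session-scoped because several downstream tests share it.
"""

from dataclasses import replace

import numpy as np
import pytest

import predgeom as pg
from predgeom import infoenc, pid, rsa
from predgeom.synthetic_data import encoder_region


@pytest.fixture(scope="session")
def hr_seq():
    return pg.generate_sequence("high", 200, seed=11)


@pytest.fixture(scope="session")
def lr_seq():
    return pg.generate_sequence("low", 200, seed=12)


@pytest.fixture(scope="session")
def hr_trace(hr_seq):
    return pg.run_observer(hr_seq)


@pytest.fixture(scope="session")
def lr_trace(lr_seq):
    return pg.run_observer(lr_seq)


@pytest.fixture(scope="session")
def atlas():
    return pg.make_atlas(0)


@pytest.fixture(scope="session")
def hr_epochs(hr_seq, hr_trace, atlas):
    cfg = replace(pg.GenConfig(), n_trials=600, seed=401)
    return pg.generate_epochs(hr_seq, hr_trace, atlas, cfg)


@pytest.fixture(scope="session")
def gen_cfg():
    return replace(pg.GenConfig(), n_trials=600, seed=401)


@pytest.fixture(scope="session")
def cohort(hr_seq, lr_seq, hr_trace, lr_trace, atlas):
    """8 virtual subjects per condition with per-subject analysis outputs.

    High regularity uses the default within-triplet convergence
    (gamma_max = 0.6); low regularity has none by construction.  For each
    subject: whole-brain window-averaged geometry slopes, the searchlight
    GCMI map and the PID network.
    """
    n_subjects = 8
    inventory = hr_seq.triplet_inventory()
    out = {"region": encoder_region(atlas, 20)}
    for cond, seq, trace in (("high", hr_seq, hr_trace), ("low", lr_seq, lr_trace)):
        within, between, model = [], [], []
        gcmi_maps, syn_mats, red_mats = [], [], []
        for s in range(n_subjects):
            cfg = replace(
                pg.GenConfig(),
                n_trials=600,
                seed=500 + s + (0 if cond == "high" else 1000),
            )
            ep = pg.generate_epochs(seq, trace, atlas, cfg)
            tidx = ep.time_window(0.110, 0.120)
            from predgeom.pipeline import _adaptive_folds, replace_data

            folds = _adaptive_folds(ep.tone, rsa.split_blocks(ep, 5), 5)
            win = replace_data(
                ep, ep.data[:, :, tidx].mean(axis=2, keepdims=True), ep.times[tidx[:1]]
            )
            series = rsa.cvmd_rdm(win, n_folds=folds)
            summ = rsa.geometry_summary(series, inventory)
            slopes = summ.slopes()
            within.append(float(slopes["within"][0]))
            between.append(float(slopes["between"][0]))
            model.append(float(slopes["model_rho"][0]))
            gcmi_maps.append(infoenc.searchlight_gcmi(ep, atlas))
            net = pid.pid_network(ep)
            syn_mats.append(net.synergy)
            red_mats.append(net.redundancy)
        out[cond] = {
            "within_slope": np.array(within),
            "between_slope": np.array(between),
            "model_slope": np.array(model),
            "gcmi_maps": np.array(gcmi_maps),
            "synergy": np.array(syn_mats),
            "redundancy": np.array(red_mats),
        }
    return out
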