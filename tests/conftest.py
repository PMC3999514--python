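import numpy as np
import pytest

import redoxeq as rq


@pytest.fixture
def myoglobin():
    return rq.heme_protein("horse myoglobin", 47.0)


@pytest.fixture
def tbo():
    return rq.get_dye("toluidine blue O")


def simulate_pair(
    protein_E_m=47.0,
    dye_name="toluidine blue O",
    noise_sd=0.002,
    seed=1,
    protein_n=1,
    dye_E_m=None,
    dye_n=None,
    **config_kwargs,
):
    """Simulate one protein/dye titration; returns (ts, truth, config)."""
    protein = rq.heme_protein("protein", protein_E_m, n=protein_n)
    dye = rq.get_dye(dye_name)
    if dye_E_m is not None or dye_n is not None:
        dye = rq.RedoxSpecies(
            name=dye.name,
            E_m_mV=dye.E_m_mV if dye_E_m is None else dye_E_m,
            n=dye.n if dye_n is None else dye_n,
            spectrum_ox=dye.spectrum_ox,
            spectrum_red=dye.spectrum_red,
        )
    cfg = rq.SimulationConfig(
        protein=protein,
        dye=dye,
        noise_sd_AU=noise_sd,
        seed=seed if noise_sd > 0 else None,
        **config_kwargs,
    )
    ts, truth = rq.simulate_run(cfg)
    return ts, truth, cfg.resolved()


@pytest.fixture
def small_timeseries():
    """A tiny hand-built series: 3 wavelengths x 4 scans, both phases."""
    return rq.SpectralTimeSeries(
        wavelengths=np.array([400.0, 410.0, 420.0]),
        times=np.array([0.0, 1.0, 2.0, 3.0]),
        absorbance=np.array(
            [
                [0.50, 0.40, 0.30, 0.25],
                [0.60, 0.55, 0.50, 0.48],
                [0.10, 0.20, 0.30, 0.35],
            ]
        ),
        phase_labels=np.array(
            ["titration", "titration", "titration", "dithionite"], dtype=object
        ),
        meta=rq.ExperimentMeta(
            temperature_K=298.15,
            pH=7.0,
            dye_name="toluidine blue O",
            protein_name="horse myoglobin",
        ),
    )
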