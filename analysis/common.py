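"""Shared study definition for the analysis drivers.

One three-cancer synthetic study at n = 300 samples per cohort; every
driver derives its inputs deterministically from STUDY, so each script can
be run independently and in any order.
"""

from pathlib import Path

from lncm6a import SimulationConfig, filter_expressed, log2_transform
from lncm6a.simulate import simulate_multi_cancer

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY = SimulationConfig(
    n_samples=300,
    n_cancers=3,
    n_lncrnas=120,
    n_mirnas=15,
    n_mrnas=150,
    n_specific_lncrnas=6,
    seed=20240915,
)


def load_study():
    """Cohorts keyed by cancer id: (log2 expression, interactions, truth)."""
    out = {}
    for cancer_id, (expr, cat, truth) in simulate_multi_cancer(STUDY).items():
        logged = log2_transform(filter_expressed(expr))
        out[cancer_id] = (logged, cat, truth)
    return out


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
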