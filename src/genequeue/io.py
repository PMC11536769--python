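"""Configuration parsing, scenario fixtures and tabular output.

Model parameter sets travel as flat YAML documents whose keys match the
:class:`~genequeue.model_core.GeneModel` field names; all rates are in
1/min.  The scenario catalogue ships the parameter sets used by the
validation experiments (threshold crossing points, timescale-separation
grids, delay-limit comparisons, case-classification examples and the
random sampling regions), so every analysis is reconstructible from
fixtures without hand-typed numbers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .model_core import GeneModel

__all__ = [
    "Scenario",
    "load_config",
    "dump_config",
    "model_from_dict",
    "model_to_dict",
    "list_scenarios",
    "get_scenario",
    "write_table",
]

_REQUIRED = {"G", "S", "R", "k_on", "k_off", "k", "delta", "delta1"}
_OPTIONAL = {"lam", "lam1", "lam2", "T_elong"}


def model_from_dict(doc: dict) -> GeneModel:
    """Validate a flat mapping into a GeneModel (strict schema)."""
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    keys = set(doc)
    missing = _REQUIRED - keys
    if missing:
        raise ValueError(f"missing config key(s): {sorted(missing)}")
    extra = keys - _REQUIRED - _OPTIONAL
    if extra:
        raise ValueError(f"unknown config key(s): {sorted(extra)}")
    if not isinstance(doc["k"], (list, tuple)):
        raise ValueError("k must be a list of per-step initiation rates")
    try:
        return GeneModel(**{k: (tuple(v) if k == "k" else v) for k, v in doc.items()})
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid model configuration: {exc}") from exc


def model_to_dict(m: GeneModel) -> dict:
    doc = asdict(m)
    doc["k"] = list(doc["k"])
    return doc


def load_config(path) -> GeneModel:
    """Load and validate a YAML model configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)


def dump_config(m: GeneModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(m), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Scenario fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """Named parameter set with optional reference quantities.

    ``expected`` carries analytic reference values (e.g. a threshold
    deactivation rate or a qualitative noise class) used by the
    validation experiments; ``extras`` holds sweep specifications for
    grid scenarios.
    """

    name: str
    description: str
    model: GeneModel | None = None
    expected: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _equal_k(G: int, k: float) -> tuple[float, ...]:
    return tuple([float(k)] * G)


def _scenarios() -> dict[str, Scenario]:
    out: dict[str, Scenario] = {}

    def add(sc: Scenario) -> None:
        out[sc.name] = sc

    # Queueing validation: Fano factor vs timescale separation (G=2, S=2)
    add(Scenario(
        name="fig2_sweep",
        description=("Random G=2, S=2 models spanning the gene/nuclear "
                     "timescale-separation parameter over [0.01, 100]; "
                     "queueing Fano factor vs simulation."),
        extras={"G": 2, "S": 2, "Lambda_range": [0.01, 100.0], "n_models": 20}))

    # Delay-limit comparisons: constitutive gene, Erlang arrivals
    add(Scenario(
        name="fig3_delay_dist",
        description=("Constitutive G=3 gene, k=10/min, nuclear retention "
                     "T_N=1 min; finite-S distributions approach the "
                     "deterministic-service law as S grows."),
        extras={"G": 3, "k": 10.0, "T_N": 1.0, "S_values": [2, 5, 10]}))
    add(Scenario(
        name="fig3_delay_fano",
        description=("Constitutive G=3 gene, k=0.2/min (15 min between "
                     "arrivals); Fano factor vs nuclear retention time."),
        extras={"G": 3, "k": 0.2, "S_values": [2, 5, 10]}))

    # ssLNA accuracy grid
    add(Scenario(
        name="fig4a_grid",
        description=("Accuracy grid for the slow-scale cytoplasmic Fano "
                     "factor: k_on in [1, 4.5], delta=delta1 in [0.08, 5]."),
        model=GeneModel(G=5, S=3, R=4, k_on=1.0, k_off=0.8, k=_equal_k(5, 300.0),
                        delta=1.0, delta1=1.0, lam=0.08),
        extras={"kon_range": [1.0, 4.5], "delta_range": [0.08, 5.0]}))

    # Threshold crossing points (cytoplasmic noise class)
    base4 = dict(G=4, S=1, R=2, delta=15.0, delta1=15.0, lam=0.3)
    add(Scenario(
        name="fig4b", description="Sub-Poissonian cytoplasmic point (FF < 1).",
        model=GeneModel(k_on=15.0, k_off=3.0, k=_equal_k(4, 46.0), **base4),
        expected={"noise_class": "sub"}))
    add(Scenario(
        name="fig4c", description="Poissonian cytoplasmic point (FF = 1, at threshold).",
        model=GeneModel(k_on=10.0, k_off=60.0, k=_equal_k(4, 40.0), **base4),
        expected={"noise_class": "poisson", "koff_threshold": 60.0}))
    add(Scenario(
        name="fig4d", description="Super-Poissonian cytoplasmic point (FF > 1).",
        model=GeneModel(k_on=5.0, k_off=50.0, k=_equal_k(4, 150.0), **base4),
        expected={"noise_class": "super"}))

    # Covariance sign-law sampling regions
    add(Scenario(
        name="cov_sign_region_1",
        description="Log-uniform sampling region for the covariance sign law (G=3).",
        extras={"G": 3, "S": 1, "R": 2, "k_off": [1.0, 60.0], "k_on": [1.0, 20.0],
                "k": [10.0, 100.0], "delta1": [10.0, 20.0], "lam": [0.13, 0.27]}))
    add(Scenario(
        name="cov_sign_region_2",
        description="Log-uniform sampling region for the covariance sign law (G=4).",
        extras={"G": 4, "S": 1, "R": 3, "k_off": [1.0, 60.0], "k_on": [1.0, 20.0],
                "k": [10.0, 100.0], "delta1": [10.0, 20.0], "lam": [0.08, 0.1]}))

    # Monotonicity-in-R demarcation region
    add(Scenario(
        name="fig4f_region",
        description=("Region for the FF-vs-R monotonicity demarcation: "
                     "k = 3 k_on + 10 along the scan."),
        extras={"G": 4, "S": 3, "k_off": [1.0, 5.0], "k_on": [1.0, 3.8],
                "delta": 15.0, "lam": 0.1}))

    # Case classification examples (distinct initiation rates)
    base_case = dict(G=3, S=1, R=3, delta=1.0, delta1=10.0, lam=0.1)
    add(Scenario(
        name="fig4g_case1", description="FF dips then returns to 1 from below.",
        model=GeneModel(k_on=8.0, k_off=1.0, k=(5.0, 4.5, 1.0), **base_case),
        expected={"case_id": 1}))
    add(Scenario(
        name="fig4g_case2", description="FF increases monotonically towards 1.",
        model=GeneModel(k_on=2.0, k_off=1.0, k=(3.0, 5.0, 2.0), **base_case),
        expected={"case_id": 2}))
    add(Scenario(
        name="fig4g_case3", description="FF peaks above 1 then decays to 1.",
        model=GeneModel(k_on=0.9, k_off=1.0, k=(4.0, 2.0, 5.0), **base_case),
        expected={"case_id": 3}))

    # Lower-bound sampling region (cytoplasmic FF >= min_ff_cyto)
    add(Scenario(
        name="ff_bound_region",
        description=("Log-uniform sampling region for the cytoplasmic "
                     "Fano-factor lower bound; S fixed to 3."),
        extras={"S": 3, "k_off": [1.0, 31.6], "k_on": [2.0, 31.6],
                "k": [10.0, 100.0], "delta": [10.0, 31.6], "lam": [0.04, 0.1]}))

    # Sensitivity ensembles (documented in the sensitivity module)
    add(Scenario(
        name="sensitivity_groups",
        description=("Three G=2, S=2 random ensembles spanning sub-, near- "
                     "and super-Poissonian nuclear noise."),
        extras={"groups": [1, 2, 3], "n": 1000}))
    return out


def list_scenarios() -> dict[str, Scenario]:
    """Catalogue of named parameter fixtures."""
    return _scenarios()


def get_scenario(name: str) -> Scenario:
    cat = _scenarios()
    if name not in cat:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(cat)}")
    return cat[name]


# ---------------------------------------------------------------------------
# Experiment builders (random ensembles tied to the scenario regions)
# ---------------------------------------------------------------------------

def timescale_sweep_models(n: int, seed: int,
                           lambda_range=(0.01, 100.0)) -> list[GeneModel]:
    """G=2, S=2 models spanning the gene/nuclear separation parameter.

    Gene-block rates are drawn log-uniformly from a band around 1/min and
    delta = delta1 is then fixed so that Lambda_{G,N} hits n log-spaced
    targets across ``lambda_range``.
    """
    import numpy as np

    from .model_core import timescales

    rng = np.random.default_rng(seed)
    targets = np.geomspace(lambda_range[0], lambda_range[1], n)
    models = []
    for lam_t in targets:
        base = GeneModel(G=2, S=2, R=1,
                         k_on=float(np.exp(rng.uniform(-0.7, 1.5))),
                         k_off=float(np.exp(rng.uniform(-0.7, 1.5))),
                         k=(float(np.exp(rng.uniform(-0.7, 1.5))),
                            float(np.exp(rng.uniform(-0.7, 1.5)))),
                         delta=1.0, delta1=1.0)
        tau_g = float(np.max(timescales(base).tau_G))
        d = lam_t / tau_g
        models.append(base.with_(delta=float(d), delta1=float(d)))
    return models


def delay_limit_model(G: int, k: float, T_N: float, S: int) -> GeneModel:
    """Constitutive finite-S model approaching the deterministic-service law.

    k_off = 0, equal initiation rates, delta = delta1 = S/T_N so the mean
    nuclear retention time stays at T_N as S grows.
    """
    d = S / T_N
    return GeneModel(G=G, S=S, R=1, k_on=1.0, k_off=0.0,
                     k=_equal_k(G, k), delta=d, delta1=d)


def cov_sign_models(region: int, n: int, seed: int) -> list[GeneModel]:
    """Log-uniform samples from the covariance sign-law regions."""
    import numpy as np

    sc = get_scenario(f"cov_sign_region_{region}")
    ex = sc.extras
    rng = np.random.default_rng(seed)

    def draw(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    models = []
    for _ in range(n):
        models.append(GeneModel(
            G=ex["G"], S=ex["S"], R=ex["R"],
            k_off=draw(*ex["k_off"]), k_on=draw(*ex["k_on"]),
            k=_equal_k(ex["G"], draw(*ex["k"])),
            delta=1.0, delta1=draw(*ex["delta1"]), lam=draw(*ex["lam"])))
    return models


def ff_bound_models(n: int, seed: int, G: int | None = 2,
                    R: int | None = None) -> list[GeneModel]:
    """Log-uniform samples from the Fano-factor lower-bound region.

    Fix either G (sampling R in 1..8) or R (sampling G in 1..6); the
    initiation rates are drawn independently per step.
    """
    import numpy as np

    ex = get_scenario("ff_bound_region").extras
    rng = np.random.default_rng(seed)

    def draw(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    models = []
    for _ in range(n):
        Gi = G if G is not None else int(rng.integers(1, 7))
        Ri = R if R is not None else int(rng.integers(1, 9))
        models.append(GeneModel(
            G=Gi, S=ex["S"], R=Ri,
            k_off=draw(*ex["k_off"]), k_on=draw(*ex["k_on"]),
            k=tuple(draw(*ex["k"]) for _ in range(Gi)),
            delta=draw(*ex["delta"]), delta1=draw(*ex["delta"]),
            lam=draw(*ex["lam"])))
    return models


def case1_models(G: int, R: int, n: int, seed: int,
                 max_tries: int = 2_000_000) -> list[GeneModel]:
    """Random models constrained to case 1 (k1 > k1*, k_on > k_on,2*).

    Rates are drawn uniformly from (0.1, 100); rejection sampling keeps
    only parameter sets in the non-monotonic (dip) regime, the case not
    covered by the analytic minimum argument.
    """
    import numpy as np

    from .lna import case_thresholds

    rng = np.random.default_rng(seed)
    models = []
    tries = 0
    while len(models) < n and tries < max_tries:
        tries += 1
        k = tuple(rng.uniform(0.1, 100.0, G))
        kon = float(rng.uniform(0.1, 100.0))
        koff = float(rng.uniform(0.1, 100.0))
        k1s, kon1s, kon2s = case_thresholds(k)
        if k[0] > k1s and kon > kon2s:
            models.append(GeneModel(G=G, S=1, R=R, k_on=kon, k_off=koff,
                                    k=k, delta=1.0, delta1=1.0, lam=1.0))
    if len(models) < n:
        raise RuntimeError("case-1 rejection sampling exhausted")
    return models


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_table(rows, path, columns=None, metadata: dict | None = None) -> None:
    """Write rows to CSV (header always present, deterministic column order).

    ``rows`` may be a DataFrame or an iterable of mappings; an optional
    JSON metadata sidecar (same path + '.meta.json') records run
    provenance such as seed and tolerances.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, index=False)
    if metadata is not None:
        from . import __version__
        meta = {"package_version": __version__, **metadata}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True))
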