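"""NONMEM-dialect longitudinal dataset I/O and declarative model configs.

Datasets are delimited text with the columns ID, TIME, AMT, DV, EVID, CMT,
MDV: each record is either a dose (EVID=1, AMT>0) or an observation
(EVID=0), times are non-decreasing within a subject, '.' marks a missing
value, and CMT is a 1-based compartment index.  Model and population
designs are loaded from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .kinetics import DoseEvent, FractalRate, ModelSpec, PKParameters

__all__ = [
    "PKDataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "load_model_config",
    "load_population_config",
]

COLUMNS = ("ID", "TIME", "AMT", "DV", "EVID", "CMT", "MDV")


class DatasetError(ValueError):
    """Dataset validation failure; message lists offending line numbers."""


@dataclass
class PKDataset:
    """Validated longitudinal PK records backed by a DataFrame.

    Dose rows have ``EVID=1`` and positive ``AMT``; observation rows have
    ``EVID=0`` with ``DV`` present unless ``MDV=1``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- queries -----------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return int(self.df["ID"].nunique())

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.df["ID"]))

    @property
    def n_observations(self) -> int:
        obs = (self.df["EVID"] == 0) & (self.df["MDV"] == 0)
        return int(obs.sum())

    def observations(self) -> pd.DataFrame:
        return self.df[(self.df["EVID"] == 0) & (self.df["MDV"] == 0)]

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def subject(self, sid) -> pd.DataFrame:
        return self.df[self.df["ID"] == sid]

    def validate(self, spec: ModelSpec | None = None) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing mandatory columns: {', '.join(missing)}")
        errors = []
        for line, row in enumerate(df.itertuples(index=False), start=2):
            evid, amt, mdv, dv = row.EVID, row.AMT, row.MDV, row.DV
            if evid not in (0, 1):
                errors.append(f"line {line}: EVID must be 0 or 1, got {evid}")
            elif evid == 1:
                if not (amt > 0):
                    errors.append(f"line {line}: dose record (EVID=1) needs AMT > 0")
            else:
                if amt > 0:
                    errors.append(f"line {line}: AMT > 0 on observation record (EVID=0)")
                if mdv not in (0, 1):
                    errors.append(f"line {line}: MDV must be 0 or 1")
                elif mdv == 0 and not np.isfinite(dv):
                    errors.append(f"line {line}: DV missing but MDV=0")
            if row.TIME < 0:
                errors.append(f"line {line}: negative TIME")
        for sid, sub in df.groupby("ID", sort=False):
            t = sub["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                errors.append(f"subject {sid}: TIME not sorted")
        if spec is not None:
            n_cmt = len(spec.compartments())
            bad = df[(df["CMT"] < 1) | (df["CMT"] > n_cmt)]
            for line in bad.index:
                errors.append(
                    f"line {line + 2}: CMT {df.loc[line, 'CMT']} outside 1..{n_cmt}"
                )
        if errors:
            raise DatasetError("; ".join(errors))

    def __eq__(self, other) -> bool:
        if not isinstance(other, PKDataset):
            return NotImplemented
        a, b = self.df[list(COLUMNS)], other.df[list(COLUMNS)]
        if len(a) != len(b):
            return False
        for c in COLUMNS:
            x, y = a[c].to_numpy(), b[c].to_numpy()
            if c == "DV":
                ok = (np.isnan(x) & np.isnan(y)) | np.isclose(
                    x, y, rtol=0, atol=0, equal_nan=True
                ) | (x == y)
                if not np.all(ok):
                    return False
            elif not np.array_equal(x, y):
                return False
        return True


def read_dataset(path, delimiter: str = ",", missing: str = ".") -> PKDataset:
    """Read and validate a NONMEM-dialect dataset from delimited text."""
    df = pd.read_csv(
        path,
        sep=delimiter,
        na_values=[missing],
        skipinitialspace=True,
        float_precision="round_trip",
    )
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetError(
            f"{path}: missing mandatory columns: {', '.join(missing_cols)}"
        )
    for c in ("TIME", "AMT", "DV"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["AMT"] = df["AMT"].fillna(0.0)
    for c in ("EVID", "CMT", "MDV"):
        df[c] = pd.to_numeric(df[c], errors="coerce").fillna(0).astype(int)
    return PKDataset(df)


def write_dataset(data: PKDataset, path) -> None:
    """Write in the fixed column order ID,TIME,AMT,DV,EVID,CMT,MDV with '.'
    for missing DV.  ``read(write(x)) == x`` field-for-field."""
    df = data.df[list(COLUMNS)].copy()
    # shortest round-trippable float text so read(write(x)) is bit-exact
    df.to_csv(path, index=False, na_rep=".", float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# Declarative YAML configs
# ---------------------------------------------------------------------------


def _spec_from_dict(d: dict) -> ModelSpec:
    fractal = {}
    for name, v in (d.get("fractal") or {}).items():
        if isinstance(v, dict):
            if "theta" in v:
                fractal[name] = FractalRate(
                    theta=float(v["theta"]),
                    h=float(v.get("h", 0.0)),
                    epsilon=float(v.get("epsilon", d.get("epsilon", 1e-6))),
                )
            else:
                fractal[name] = float(v["h"])
        else:
            fractal[name] = float(v)
    fracs = d.get("dose_fractions")
    if fracs is not None:
        fracs = tuple((float(f["fraction"]), str(f["route"])) for f in fracs)
    return ModelSpec(
        n_compartments=int(d.get("compartments", 1)),
        absorption=str(d.get("absorption", "first_order")),
        n_transit=int(d.get("n_transit", 3)),
        ktr=float(d.get("ktr", 1.0)),
        fractal_on=fractal,
        dose_fractions=fracs,
        reset_on_dose=bool(d.get("reset_on_dose", False)),
        epsilon=float(d.get("epsilon", 1e-6)),
    )


def spec_to_dict(spec: ModelSpec) -> dict:
    """Serializable form of a ModelSpec; inverse of the config parser."""
    fractal = {}
    for name, v in spec.fractal_on.items():
        if isinstance(v, FractalRate):
            fractal[name] = {"theta": v.theta, "h": v.h, "epsilon": v.epsilon}
        else:
            fractal[name] = float(v)
    d = {
        "compartments": spec.n_compartments,
        "absorption": spec.absorption,
        "n_transit": spec.n_transit,
        "ktr": spec.ktr,
        "fractal": fractal,
        "reset_on_dose": spec.reset_on_dose,
        "epsilon": spec.epsilon,
    }
    if spec.dose_fractions is not None:
        d["dose_fractions"] = [
            {"fraction": f, "route": r} for f, r in spec.dose_fractions
        ]
    return d


def _params_from_dict(d: dict) -> PKParameters:
    return PKParameters(
        CL=float(d["CL"]),
        V1=float(d["V1"]),
        Ka=float(d["Ka"]) if "Ka" in d else None,
        Q=float(d["Q"]) if "Q" in d else None,
        V2=float(d["V2"]) if "V2" in d else None,
    )


def _doses_from_list(items: Iterable[dict]) -> list[DoseEvent]:
    return [
        DoseEvent(time=float(x["time"]), amount=float(x["amount"]), cmt=x.get("cmt"))
        for x in items
    ]


def load_model_config(path):
    """Load a simulation config: returns (spec, params, doses, output_times)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    spec = _spec_from_dict(cfg.get("model", {}))
    params = _params_from_dict(cfg["parameters"])
    doses = _doses_from_list(cfg.get("doses", []))
    times_cfg = cfg.get("times", {})
    if isinstance(times_cfg, list):
        times = np.asarray(times_cfg, dtype=float)
    else:
        times = np.arange(
            float(times_cfg.get("start", 0.0)),
            float(times_cfg.get("stop", 400.0)) + 1e-9,
            float(times_cfg.get("step", 0.5)),
        )
    return spec, params, doses, times


def load_population_config(path):
    """Load a population design config.

    Returns a :class:`fractalpk.population.PopulationDesign`.  The YAML
    mirrors the model config plus a ``population`` block (n_subjects,
    omega, sigma, sampling_times, optional seed).
    """
    from .population import PopulationDesign, PopulationModel

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    spec = _spec_from_dict(cfg.get("model", {}))
    pop = cfg["population"]
    theta = {k: float(v) for k, v in cfg["parameters"].items()}
    model = PopulationModel(
        spec=spec,
        theta=theta,
        omega={k: float(v) for k, v in (pop.get("omega") or {}).items()},
        sigma_add=float((pop.get("sigma") or {}).get("add", 0.0)),
        sigma_prop=float((pop.get("sigma") or {}).get("prop", 0.0)),
    )
    return PopulationDesign(
        model=model,
        n_subjects=int(pop["n_subjects"]),
        doses=_doses_from_list(cfg.get("doses", [])),
        sampling_times=tuple(float(t) for t in pop["sampling_times"]),
        seed=pop.get("seed"),
        truncate_negative=bool(pop.get("truncate_negative", False)),
    )
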