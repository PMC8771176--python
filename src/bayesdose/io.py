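"""Reading and writing the tabular interchange formats.

Trial data travel as CSV (columns ``arm_label, n_patients, n_dlt``, control
first) or JSON; design configurations as YAML/JSON; scenarios as CSV with
one row per scenario (``name, target_arm, p0, p1, ...``); reports and
operating characteristics as CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import DesignConfig
from .model import TrialData
from .simulate import OperatingCharacteristics, Scenario

__all__ = [
    "read_trial_data",
    "write_trial_data",
    "read_design",
    "write_design",
    "read_scenarios",
    "write_scenarios",
    "write_operating_characteristics",
]


def read_trial_data(path: str | Path) -> TrialData:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return TrialData(np.asarray(payload["n_patients"]), np.asarray(payload["n_dlt"]))
    df = pd.read_csv(path)
    required = {"arm_label", "n_patients", "n_dlt"}
    if not required.issubset(df.columns):
        raise ValueError(f"trial data needs columns {sorted(required)}")
    return TrialData(df["n_patients"].to_numpy(), df["n_dlt"].to_numpy())


def write_trial_data(
    data: TrialData, path: str | Path, labels: list[str] | None = None
) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(
            json.dumps(
                {"n_patients": data.n_patients.tolist(), "n_dlt": data.n_dlt.tolist()},
                indent=2,
            )
        )
        return
    labels = labels or (["control"] + [f"dose_{j}" for j in range(1, data.n_arms)])
    pd.DataFrame(
        {"arm_label": labels, "n_patients": data.n_patients, "n_dlt": data.n_dlt}
    ).to_csv(path, index=False)


def read_design(path: str | Path) -> DesignConfig:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return DesignConfig.from_dict(payload)


def write_design(design: DesignConfig, path: str | Path) -> None:
    path = Path(path)
    payload = design.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_scenarios(path: str | Path) -> list[Scenario]:
    df = pd.read_csv(path)
    p_cols = sorted(
        (c for c in df.columns if c.startswith("p") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    out = []
    for _, row in df.iterrows():
        target = row.get("target_arm")
        target = None if pd.isna(target) else int(target)
        out.append(
            Scenario(
                name=str(row["name"]),
                true_p=tuple(float(row[c]) for c in p_cols),
                target_arm=target,
            )
        )
    return out


def write_scenarios(scenarios: list[Scenario], path: str | Path) -> None:
    rows = []
    for sc in scenarios:
        row = {"name": sc.name, "target_arm": sc.target_arm}
        row.update({f"p{j}": p for j, p in enumerate(sc.true_p)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_operating_characteristics(
    oc: OperatingCharacteristics, path: str | Path
) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(oc.to_dict(), indent=2))
        return
    m = len(oc.selection_prop)
    row = {"scenario": oc.scenario}
    row.update({f"select_d{j + 1}": oc.selection_prop[j] for j in range(m)})
    row.update(
        {
            "stop_prop": oc.stop_prop,
            "over_toxic_selection_prop": oc.over_toxic_selection_prop,
            "mean_dlts": oc.mean_dlts,
            "n_sims": oc.n_sims,
            "seed": oc.seed,
        }
    )
    pd.DataFrame([row]).to_csv(path, index=False)
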