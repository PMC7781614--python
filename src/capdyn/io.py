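"""Plain-text cohort I/O.

On-disk layout (all whitespace/tab-delimited text):

* ``participants.tsv``        participant_id, group, site, age, sex, handedness
* ``components.tsv``          component_id, network, noise, is_seed
* ``<subject>_timeseries.tsv``  header = component ids, one row per frame
* ``rp_<subject>.txt``        SPM-style 6-column realignment parameters
* ``fd_<subject>.txt``        alternatively, a one-column precomputed FD trace
* ``truth.json``              planted generator parameters (synthetic cohorts)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import HANDEDNESS_LEVELS, CohortSchemaError, ComponentTimeSeries
from .synthetic import SyntheticCohort

PARTICIPANT_COLUMNS = ("participant_id", "group", "site", "age", "sex", "handedness")


def _fmt(a: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(a)


def write_cohort(out_dir: str | Path, cohort: SyntheticCohort) -> Path:
    """Write a synthetic cohort to ``out_dir`` in the plain-text layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out / "participants.tsv", sep="\t", index=False)

    ref = cohort.subjects[0]
    pd.DataFrame(
        {
            "component_id": ref.component_ids,
            "network": ref.network_labels,
            "noise": ref.noise_flags.astype(int),
            "is_seed": [int(c == ref.seed_component) for c in ref.component_ids],
        }
    ).to_csv(out / "components.tsv", sep="\t", index=False)

    for ts in cohort.subjects:
        pd.DataFrame(ts.data, columns=list(ts.component_ids)).to_csv(
            out / f"{ts.subject_id}_timeseries.tsv", sep="\t", index=False
        )
    for sid, rp in cohort.realignment.items():
        np.savetxt(out / f"rp_{sid}.txt", rp, fmt="%.10g")

    truth = cohort.truth
    payload = {
        "config": dataclasses.asdict(truth.config),
        "patterns": truth.pattern_set.patterns.tolist(),
        "seed_component": truth.pattern_set.seed_component,
        "amplitude": truth.pattern_set.amplitude,
        "network_labels": list(truth.pattern_set.network_labels),
        "true_labels": {s: lab.tolist() for s, lab in truth.true_labels.items()},
        "tr_seconds": truth.config.tr_seconds,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return out


def _read_numeric_table(path: Path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited numeric table, locating any non-numeric cell."""
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise CohortSchemaError(
            f"{path.name}: non-numeric value {raw.iat[r, c]!r} at data row "
            f"{r}, column {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise CohortSchemaError(f"{path.name}: missing values present")
    return numeric


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PARTICIPANT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortSchemaError(f"participants.tsv missing columns: {sorted(missing)}")
    bad = df[~df["handedness"].isin(HANDEDNESS_LEVELS)]
    if len(bad):
        rows = bad.index.tolist()
        raise CohortSchemaError(
            f"participants.tsv: unknown handedness code(s) "
            f"{sorted(bad['handedness'].unique())} at row(s) {rows}"
        )
    if df["participant_id"].duplicated().any():
        raise CohortSchemaError("participants.tsv: duplicate participant ids")
    return df


def read_cohort(
    input_dir: str | Path,
) -> tuple[list[ComponentTimeSeries], pd.DataFrame, dict[str, np.ndarray]]:
    """Load a cohort directory; returns (subjects, participants, motion).

    ``motion[sid]`` is a (T, 6) realignment matrix or a (T,) FD trace,
    whichever file is present. Subjects listed in participants.tsv
    without a time-series file raise an error naming them.
    """
    root = Path(input_dir)
    participants = read_participants(root / "participants.tsv")
    comp = pd.read_csv(root / "components.tsv", sep="\t")
    for col in ("component_id", "network", "noise", "is_seed"):
        if col not in comp.columns:
            raise CohortSchemaError(f"components.tsv missing column {col!r}")
    seed_rows = comp[comp["is_seed"] == 1]
    if len(seed_rows) != 1:
        raise CohortSchemaError("components.tsv must flag exactly one seed component")
    seed_id = str(seed_rows["component_id"].iloc[0])
    comp_ids = tuple(str(c) for c in comp["component_id"])

    tr = 2.0
    truth_path = root / "truth.json"
    if truth_path.exists():
        tr = float(json.loads(truth_path.read_text()).get("tr_seconds", tr))

    missing = [
        sid
        for sid in participants["participant_id"]
        if not (root / f"{sid}_timeseries.tsv").exists()
    ]
    if missing:
        raise CohortSchemaError(f"no time-series file for subject(s): {missing}")

    subjects, motion = [], {}
    for sid in participants["participant_id"]:
        table = _read_numeric_table(root / f"{sid}_timeseries.tsv")
        if tuple(table.columns) != comp_ids:
            raise CohortSchemaError(
                f"{sid}: component columns disagree with components.tsv"
            )
        subjects.append(
            ComponentTimeSeries(
                subject_id=sid,
                data=table.to_numpy(dtype=float),
                tr_seconds=tr,
                component_ids=comp_ids,
                noise_flags=comp["noise"].to_numpy(dtype=bool),
                network_labels=tuple(str(n) for n in comp["network"]),
                seed_component=seed_id,
            )
        )
        rp_path = root / f"rp_{sid}.txt"
        fd_path = root / f"fd_{sid}.txt"
        if rp_path.exists():
            rp = np.loadtxt(rp_path)
            if rp.ndim != 2 or rp.shape[1] != 6:
                raise CohortSchemaError(f"{rp_path.name}: expected 6 columns")
            motion[sid] = rp
        elif fd_path.exists():
            motion[sid] = np.loadtxt(fd_path).reshape(-1)
        else:
            raise CohortSchemaError(f"no motion file (rp_/fd_) for subject {sid}")
    return subjects, participants, motion
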