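"""File formats: phenotype CSV, cohort connectome containers, reports.

Phenotypes travel as plain CSV (header: subject_id,sex,condition,age,icv,
mfd,dvars,spike_pct). Connectome stacks are stored in a compressed NumPy
archive keyed by subject id (one 3x116x116 float array per key); time
series use the same container or per-subject CSV. Retained-id lists are one
id per line; certificates and fits are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .balancing import BalanceCertificate
from .cohort import PHENOTYPE_COLUMNS


def save_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=list(PHENOTYPE_COLUMNS))


def load_phenotypes(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return table


def save_connectomes(stacks: np.ndarray, subject_ids, path) -> None:
    """Write (n, 3, 116, 116) stacks keyed by subject id (.npz, compressed)."""
    arrays = {str(sid): stacks[i].astype(np.float32)
              for i, sid in enumerate(subject_ids)}
    np.savez_compressed(path, **arrays)


def load_connectomes(path, subject_ids=None):
    """Read a cohort container; returns (stacks, subject_ids) in stored or
    requested order."""
    with np.load(path) as data:
        ids = list(data.files) if subject_ids is None else [
            str(s) for s in subject_ids
        ]
        stacks = np.stack([data[sid] for sid in ids]).astype(np.float64)
    return stacks, np.array(ids)


def save_timeseries_csv(series: np.ndarray, path) -> None:
    """One subject's T x 116 series as CSV, columns parcel_000..parcel_115."""
    cols = [f"parcel_{i:03d}" for i in range(series.shape[1])]
    pd.DataFrame(series, columns=cols).to_csv(path, index=False)


def load_timeseries_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)


def save_id_list(ids, path) -> None:
    Path(path).write_text("\n".join(str(i) for i in ids) + "\n")


def load_id_list(path) -> list[str]:
    return [ln for ln in Path(path).read_text().splitlines() if ln.strip()]


def save_certificate(cert: BalanceCertificate, path) -> None:
    payload = asdict(cert)
    payload["p_values"] = {k: (None if np.isnan(v) else float(v))
                           for k, v in payload["p_values"].items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)}")
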