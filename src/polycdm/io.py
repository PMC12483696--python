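"""CSV/JSON/YAML input and output.

Responses and Q-matrices travel as headered CSV; fitted parameters and fit
statistics as nested, schema-versioned JSON; posteriors and classifications
as CSV.  Missing responses are rejected outright — the models assume
complete data — and every parse error names the offending file, row, and
column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attribute_space import AttributeSpec, QMatrix
from .estimation import FitResult, fit_statistics

__all__ = [
    "read_responses",
    "write_responses",
    "read_qmatrix",
    "write_qmatrix",
    "load_config",
    "fit_to_dict",
    "save_fit",
    "save_posteriors",
]

SCHEMA_VERSION = 1


class ParseError(ValueError):
    pass


def read_responses(path: str | Path) -> tuple[np.ndarray, list[str], list[str] | None]:
    """Read a binary response matrix.

    Expects a header row of item IDs and {0,1} cells; a first column named
    ``id`` (case-insensitive) is treated as examinee IDs.  Returns
    ``(N x J matrix, item_ids, examinee_ids-or-None)``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    examinee_ids = None
    if df.columns[0].strip().lower() in ("id", "examinee", "person"):
        examinee_ids = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-binary response {values[r, c]!r} at row {r + 2}, "
            f"column {df.columns[c]!r}"
        )
    return values.astype(int), [str(c) for c in df.columns], examinee_ids


def write_responses(path: str | Path, X: np.ndarray, item_ids: list[str] | None = None) -> None:
    X = np.asarray(X, dtype=int)
    cols = item_ids or [f"item{j + 1}" for j in range(X.shape[1])]
    pd.DataFrame(X, columns=cols).to_csv(path, index=False)


def read_qmatrix(path: str | Path, spec: AttributeSpec) -> QMatrix:
    """Read and validate a Q-matrix CSV (header row of attribute names)."""
    path = Path(path)
    df = pd.read_csv(path)
    entries = df.to_numpy()
    if not np.issubdtype(entries.dtype, np.integer):
        try:
            entries = entries.astype(int)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-integer Q-matrix entries") from exc
    try:
        return QMatrix(entries, spec)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_qmatrix(path: str | Path, Q: QMatrix, names: list[str] | None = None) -> None:
    cols = names or [f"attr{k + 1}" for k in range(Q.spec.n_attributes)]
    pd.DataFrame(Q.entries, columns=cols).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def fit_to_dict(fit: FitResult) -> dict:
    stats = fit_statistics(fit)
    return {
        "schema_version": SCHEMA_VERSION,
        "levels": list(fit.spec.levels),
        "items": [
            {
                "kind": m.kind,
                "link": m.link,
                "q_row": list(m.q_row),
                "delta": m.delta.tolist() if m.delta is not None else None,
                "group_probabilities": fit.group_probs[j].tolist(),
                "groups": m.partition.groups.tolist(),
                "se": None
                if fit.se is None
                else [
                    float(s) if bool(a) else None
                    for s, a in zip(fit.se[j], fit.se_available[j])
                ],
            }
            for j, m in enumerate(fit.item_models)
        ],
        "pi": fit.pi.tolist(),
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "fit_statistics": {
            "deviance": stats.deviance,
            "aic": stats.aic,
            "bic": stats.bic,
            "n_parameters": stats.n_parameters,
        },
    }


def save_fit(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=1))


def save_posteriors(fit: FitResult, path: str | Path) -> None:
    pd.DataFrame(fit.posterior).to_csv(path, index=False)
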