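"""Plain-text readers and writers for the package's tabular schemas.

Exposure tables carry site coordinates, interval endpoints and values;
block tables carry WKT polygons and interval endpoints; outcome tables carry
block ids, outcome values and confounder columns.  Posterior draws are
serialized in a long (draw, model, parameter, value) format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .supports import BlockSupport, PointSupport, TimeInterval, polygon_from_wkt

__all__ = [
    "write_exposure_csv",
    "read_exposure_csv",
    "write_blocks_csv",
    "read_blocks_csv",
    "write_outcome_csv",
    "read_outcome_csv",
    "write_draws_csv",
    "read_draws_csv",
    "write_weights_csv",
    "read_weights_csv",
    "write_loo_csv",
]


def write_exposure_csv(supports: list[PointSupport], x: np.ndarray, path) -> None:
    df = pd.DataFrame(
        {
            "site_id": np.arange(len(supports)),
            "x": [s.site[0] for s in supports],
            "y": [s.site[1] for s in supports],
            "t_start": [s.interval.a for s in supports],
            "t_end": [s.interval.b for s in supports],
            "value": np.asarray(x, dtype=float),
        }
    )
    df.to_csv(path, index=False)


def read_exposure_csv(path) -> tuple[list[PointSupport], np.ndarray]:
    df = pd.read_csv(path)
    supports = [
        PointSupport(site=(row.x, row.y), interval=TimeInterval(row.t_start, row.t_end))
        for row in df.itertuples()
    ]
    return supports, df["value"].to_numpy(dtype=float)


def write_blocks_csv(blocks: list[BlockSupport], path) -> None:
    df = pd.DataFrame(
        {
            "block_id": np.arange(len(blocks)),
            "wkt": [b.polygon.wkt for b in blocks],
            "t_start": [b.interval.a for b in blocks],
            "t_end": [b.interval.b for b in blocks],
        }
    )
    df.to_csv(path, index=False)


def read_blocks_csv(path) -> list[BlockSupport]:
    df = pd.read_csv(path)
    return [
        BlockSupport(
            polygon=polygon_from_wkt(row.wkt),
            interval=TimeInterval(row.t_start, row.t_end),
        )
        for row in df.itertuples()
    ]


def write_outcome_csv(y: np.ndarray, W: np.ndarray, path) -> None:
    data = {"block_id": np.arange(len(y)), "y": np.asarray(y, dtype=float)}
    W = np.atleast_2d(W)
    for i in range(W.shape[1]):
        data[f"w{i + 1}"] = W[:, i]
    pd.DataFrame(data).to_csv(path, index=False)


def read_outcome_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path).sort_values("block_id")
    wcols = [c for c in df.columns if c.startswith("w")]
    return df["y"].to_numpy(dtype=float), df[wcols].to_numpy(dtype=float)


def write_draws_csv(draws: dict[str, np.ndarray], path, model: str = "") -> None:
    """Long-format serialization: draw index, model id, parameter name, value."""
    rows = []
    for name, arr in draws.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[0] == 1 and arr.size > 1:
            arr = arr.T
        for b in range(arr.shape[0]):
            for i in range(arr.shape[1]):
                pname = name if arr.shape[1] == 1 else f"{name}[{i}]"
                rows.append((b, model, pname, arr[b, i]))
    pd.DataFrame(rows, columns=["draw", "model", "parameter", "value"]).to_csv(
        path, index=False
    )


def read_draws_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_weights_csv(model_ids: list[str], alpha: np.ndarray, path) -> None:
    pd.DataFrame({"model": model_ids, "weight": np.asarray(alpha, dtype=float)}).to_csv(
        path, index=False
    )


def read_weights_csv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return df["model"].tolist(), df["weight"].to_numpy(dtype=float)


def write_loo_csv(lpd: np.ndarray, model_ids: list[str], path,
                  pareto_k: np.ndarray | None = None) -> None:
    df = pd.DataFrame(lpd, columns=model_ids)
    df.insert(0, "obs", np.arange(lpd.shape[0]))
    if pareto_k is not None:
        for g, mid in enumerate(model_ids):
            df[f"k:{mid}"] = pareto_k[:, g]
    df.to_csv(path, index=False)
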