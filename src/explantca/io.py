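"""File formats: masks as PNG, fields as TIFF/CSV, configs as YAML,
summaries as CSV, pilot libraries and posteriors as JSON + CSV."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .aabc import PilotLibrary, PosteriorSample, PriorSpec
from .morphometrics import SummaryDataset

__all__ = [
    "read_mask",
    "write_mask",
    "write_field",
    "load_config",
    "save_config",
    "summaries_to_frame",
    "frame_to_summaries",
    "save_pilot_library",
    "load_pilot_library",
    "save_posterior",
    "write_manifest",
]


def read_mask(path) -> np.ndarray:
    """Read a 0/255 PNG (or any grayscale image) as a boolean raster."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def write_mask(path, mask) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool).astype(np.uint8) * 255))


def write_field(path, values) -> None:
    """Write a field snapshot as 32-bit TIFF or CSV grid (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    else:
        np.savetxt(path, np.asarray(values), delimiter=",")


def save_config(path, config) -> None:
    """Write a RunConfig (or any to_dict-able object) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path):
    from .experiments import RunConfig

    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def summaries_to_frame(datasets) -> pd.DataFrame:
    """Long-format frame: replicate_id, time_h, normalised_area, branch_count."""
    rows = []
    for d in datasets:
        for t, a, b in zip(d.times_h, d.normalised_area, d.branch_counts):
            rows.append(
                {"replicate_id": d.replicate_id, "time_h": float(t),
                 "normalised_area": float(a), "branch_count": int(b)}
            )
    return pd.DataFrame(rows)


def frame_to_summaries(frame: pd.DataFrame) -> list:
    """Inverse of :func:`summaries_to_frame`."""
    out = []
    for rid, grp in frame.groupby("replicate_id"):
        grp = grp.sort_values("time_h")
        out.append(
            SummaryDataset(
                times_h=grp["time_h"].to_numpy(),
                normalised_area=grp["normalised_area"].to_numpy(),
                branch_counts=grp["branch_count"].to_numpy(),
                replicate_id=int(rid),
            )
        )
    return out


def save_pilot_library(directory, library: PilotLibrary) -> None:
    """Persist a pilot library as thetas.json + summaries.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "thetas": library.thetas.tolist(),
        "times_h": library.times_h.tolist(),
        "n_replicates": library.n_replicates,
        "prior": {
            "c1": list(library.prior.c1),
            "c2": list(library.prior.c2),
            "p_move": list(library.prior.p_move),
        },
    }
    with open(directory / "thetas.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    m, n, d = library.summaries.shape
    frame = pd.DataFrame(
        library.summaries.reshape(m * n, d),
        columns=[f"s{j}" for j in range(d)],
    )
    frame.insert(0, "particle", np.repeat(np.arange(m), n))
    frame.insert(1, "replicate", np.tile(np.arange(n), m))
    frame.to_csv(directory / "summaries.csv", index=False)


def load_pilot_library(directory) -> PilotLibrary:
    directory = Path(directory)
    with open(directory / "thetas.json") as fh:
        meta = json.load(fh)
    frame = pd.read_csv(directory / "summaries.csv")
    thetas = np.asarray(meta["thetas"], dtype=float)
    m = thetas.shape[0]
    n = int(meta["n_replicates"])
    cols = [c for c in frame.columns if c.startswith("s")]
    summaries = frame[cols].to_numpy().reshape(m, n, len(cols))
    prior = PriorSpec(**{k: tuple(v) for k, v in meta["prior"].items()})
    return PilotLibrary(
        thetas=thetas, summaries=summaries,
        times_h=np.asarray(meta["times_h"], dtype=float), prior=prior,
    )


def save_posterior(path, posterior: PosteriorSample) -> None:
    """Posterior sample as JSON records {c1, c2, p_move, distance}."""
    records = [
        {"c1": float(t[0]), "c2": float(t[1]), "p_move": float(t[2]),
         "distance": float(d)}
        for t, d in zip(posterior.thetas, posterior.distances)
    ]
    payload = {
        "epsilon": None if np.isinf(posterior.epsilon) else float(posterior.epsilon),
        "acceptance_fraction": posterior.acceptance_fraction,
        "n_accepted": posterior.n_accepted,
        "samples": records,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_manifest(path, **entries) -> None:
    """Run provenance: resolved config, seeds, package version, digests."""
    from . import __version__

    payload = {"package": "explantca", "version": __version__}
    payload.update(entries)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
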