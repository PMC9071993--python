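"""Dataset containers and model archives.

Epoched EEG fixtures are stored as NumPy ``.npz`` archives with datasets
``data`` (trials x channels x samples), ``labels`` and ``fs``; fitted
models serialize to a single ``.npz`` with a ``kind`` tag.  A reader for
GDF recordings (the format of the public four-class motor-imagery
competition sets) is provided behind an optional ``mne`` dependency; the
core library never requires it.
"""

from __future__ import annotations

import numpy as np

from .bilinear import BilinearModel, SeparableScatter
from .core import EpochedEEG, ValidationError, validate_epochs
from .embeddings import EmbeddingModel


def save_epochs(path, epochs: EpochedEEG) -> None:
    """Write an EpochedEEG to an .npz container."""
    extra = {}
    if epochs.channel_names is not None:
        extra["channel_names"] = np.array(epochs.channel_names, dtype=str)
    np.savez_compressed(
        path, data=epochs.data, labels=epochs.labels, fs=np.array(epochs.fs), **extra
    )


def load_epochs(path) -> EpochedEEG:
    """Load and re-validate an EpochedEEG from an .npz container."""
    with np.load(path, allow_pickle=False) as f:
        names = [str(c) for c in f["channel_names"]] if "channel_names" in f else None
        return validate_epochs(f["data"], f["labels"], float(f["fs"]), channel_names=names)


def save_bilinear_model(path, model: BilinearModel) -> None:
    np.savez_compressed(
        path,
        kind=np.array("b2ddlpp"),
        U=model.U,
        V=model.V,
        lam=model.lam,
        gamma=model.gamma,
        selection_order=np.array(model.selection_order, dtype=np.int64),
        t=np.array(model.t),
        ridge=np.array(model.ridge),
        psi=model.scatter.psi,
        phi=model.scatter.phi,
        S_BL=model.scatter.S_BL,
        S_BR=model.scatter.S_BR,
    )


def load_bilinear_model(path) -> BilinearModel:
    with np.load(path, allow_pickle=False) as f:
        if str(f["kind"]) != "b2ddlpp":
            raise ValidationError(f"archive holds a {f['kind']} model, not b2ddlpp")
        return BilinearModel(
            U=f["U"],
            V=f["V"],
            lam=f["lam"],
            gamma=f["gamma"],
            selection_order=tuple((int(l), int(j)) for l, j in f["selection_order"]),
            t=float(f["t"]),
            ridge=float(f["ridge"]),
            scatter=SeparableScatter(
                psi=f["psi"], phi=f["phi"], S_BL=f["S_BL"], S_BR=f["S_BR"]
            ),
        )


def save_embedding_model(path, model: EmbeddingModel) -> None:
    np.savez_compressed(
        path,
        kind=np.array(model.kind),
        projection=model.projection,
        eigenvalues=model.eigenvalues,
        d=np.array(model.d),
        n_f=np.array(model.n_f),
        n_g=np.array(model.n_g),
        t=np.array(model.t if model.t is not None else np.nan),
    )


def load_embedding_model(path) -> EmbeddingModel:
    with np.load(path, allow_pickle=False) as f:
        t = float(f["t"])
        return EmbeddingModel(
            kind=str(f["kind"]),
            projection=f["projection"],
            eigenvalues=f["eigenvalues"],
            d=int(f["d"]),
            n_f=int(f["n_f"]),
            n_g=int(f["n_g"]),
            t=None if np.isnan(t) else t,
        )


def read_gdf(path, event_ids=None, tmin: float = 0.0, tmax: float = 3.0) -> EpochedEEG:
    """Read epoched trials from a GDF recording (requires ``mne``).

    EOG channels are dropped with a log notice; cue annotations are
    mapped to class labels via ``event_ids`` (annotation value -> class).
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading GDF files requires the optional dependency mne "
            "(pip install mifex[eeg-io])"
        ) from err
    import logging

    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    eog = [ch for ch in raw.ch_names if "EOG" in ch.upper()]
    if eog:
        logging.getLogger(__name__).info("dropping EOG channels: %s", eog)
        raw.drop_channels(eog)
    events, ann_map = mne.events_from_annotations(raw, verbose="error")
    if event_ids is None:
        event_ids = {k: v for k, v in ann_map.items() if k in ("769", "770", "771", "772")}
    picked = {k: ann_map[k] for k in event_ids if k in ann_map}
    epochs = mne.Epochs(
        raw, events, event_id=picked, tmin=tmin, tmax=tmax,
        baseline=None, preload=True, verbose="error",
    )
    labels = epochs.events[:, 2]
    return validate_epochs(epochs.get_data(), labels, raw.info["sfreq"],
                           channel_names=list(epochs.ch_names))
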