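"""EEG file formats, metric-table export, and run manifests.

Reading uses the established readers in MNE-Python: BrainVision
(``.vhdr``/``.vmrk``/``.eeg``) and EEGLAB (``.set``).  Writing targets the
EEGLAB ``.set`` format (a MATLAB file, written through ``scipy.io.savemat``
so the output is readable by EEGLAB and by ``mne.io.read_raw_eeglab``).
Simulation metadata (dataset kind, seed, scenario hash) rides along in the
EEG structure's ``etc`` field and survives a round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .forward import EEGDataset

__all__ = ["read_eeg", "write_eeg", "export_metrics_table", "write_manifest"]


def read_eeg(path: str | Path, format: Optional[str] = None) -> EEGDataset:
    """Read a multichannel EEG recording into an :class:`EEGDataset`.

    ``format`` is inferred from the extension when omitted: ``.vhdr`` ->
    BrainVision, ``.set`` -> EEGLAB.  Potentials are returned in microvolts.
    A missing BrainVision marker file degrades to a warning (markers are not
    used here); structural problems (header/data mismatches) raise.
    """
    import mne

    path = Path(path)
    if format is None:
        format = {".vhdr": "brainvision", ".set": "eeglab_set"}.get(path.suffix.lower())
    if format == "brainvision":
        _check_brainvision_sizes(path)
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif format == "eeglab_set":
        raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    else:
        raise ValueError(f"cannot infer EEG format for {path.name!r}")
    data_uv = raw.get_data() * 1e6
    meta = {"source_file": path.name, "format": format}
    kind, seed = "mix", None
    if format == "eeglab_set":
        etc = _read_set_etc(path)
        if etc:
            kind = etc.get("kind", kind)
            seed = etc.get("seed", seed)
            meta.update(etc)
    return EEGDataset(
        data=data_uv,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        kind=kind,
        seed=seed,
        metadata=meta,
    )


_BV_SAMPLE_BYTES = {"IEEE_FLOAT_32": 4, "INT_16": 2, "INT_32": 4}


def _check_brainvision_sizes(path: Path) -> None:
    """Reject binaries whose length contradicts the declared channel count."""
    header = path.read_text(errors="replace")
    fields = {}
    for line in header.splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    try:
        n_chan = int(fields["NumberOfChannels"])
    except (KeyError, ValueError):
        raise ValueError("malformed BrainVision header: NumberOfChannels missing")
    data_file = path.parent / fields.get("DataFile", path.with_suffix(".eeg").name)
    nbytes = _BV_SAMPLE_BYTES.get(fields.get("BinaryFormat", "IEEE_FLOAT_32"), 4)
    if data_file.exists() and data_file.stat().st_size % (n_chan * nbytes):
        raise ValueError(
            f"BrainVision binary size {data_file.stat().st_size} is not a "
            f"multiple of NumberOfChannels={n_chan} x {nbytes} bytes")


def _read_set_etc(path: Path) -> dict:
    """Recover the JSON metadata blob embedded in a .set file, if any."""
    import scipy.io

    try:
        mat = scipy.io.loadmat(path, squeeze_me=True, struct_as_record=False,
                               variable_names=["EEG"])
        etc = getattr(mat["EEG"], "etc", None)
        blob = getattr(etc, "assrmix_json", None) if etc is not None else None
        if isinstance(blob, str) and blob:
            return json.loads(blob)
    except Exception:
        pass
    return {}


def write_eeg(ds: EEGDataset, path: str | Path) -> Path:
    """Write a dataset as an EEGLAB ``.set`` file (data embedded, float32).

    The kind tag, seed and scenario metadata are stored as a JSON string in
    ``EEG.etc.assrmix_json``.  Identical inputs produce byte-identical
    files.
    """
    import scipy.io

    path = Path(path)
    if path.suffix.lower() != ".set":
        raise ValueError("EEGLAB export requires a .set path")
    n_chan, n_samp = ds.data.shape
    chanlocs = np.array([(lab,) for lab in ds.channel_labels], dtype=[("labels", "O")])
    meta = {k: v for k, v in ds.metadata.items()
            if isinstance(v, (str, int, float, bool, type(None)))}
    blob = json.dumps({"kind": ds.kind, "seed": ds.seed, **meta}, sort_keys=True)
    eeg = dict(
        setname=f"assrmix-{ds.kind}",
        data=ds.data.astype(np.float32),
        srate=float(ds.sampling_rate_hz),
        nbchan=n_chan,
        pnts=n_samp,
        trials=1,
        xmin=0.0,
        xmax=(n_samp - 1) / ds.sampling_rate_hz,
        chanlocs=chanlocs,
        icawinv=np.empty((0, 0)),
        icaweights=np.empty((0, 0)),
        icasphere=np.empty((0, 0)),
        event=np.empty((0,)),
        etc={"assrmix_json": blob},
    )
    scipy.io.savemat(path, {"EEG": eeg}, appendmat=False, do_compression=False)
    return path


def export_metrics_table(df, path: str | Path, scenario=None) -> Path:
    """Write a tidy metrics table as TSV, with scenario metadata columns."""
    path = Path(path)
    out = df.copy()
    if scenario is not None:
        out["scenario_hash"] = scenario.config_hash()
        out["scenario_seed"] = scenario.seed
    out.to_csv(path, sep="\t", index=False)
    return path


def write_manifest(path: str | Path, scenario, seeds, extra: Optional[dict] = None) -> Path:
    """Write the reproducibility manifest for a run (config + seeds + versions)."""
    import numpy
    import scipy
    import sklearn

    path = Path(path)
    manifest = {
        "config": scenario.model_dump(),
        "config_hash": scenario.config_hash(),
        "seeds": list(map(int, seeds)),
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path
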