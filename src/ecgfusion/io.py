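"""Reading and writing ECG records, beat segments, images and manifests.

Signals travel as plain CSV (one column per lead, optional header of lead
names) with the sampling rate in a YAML sidecar or passed explicitly;
WFDB-style header/.dat record pairs (format 16) are also readable. Beats
are persisted one compressed archive per source record plus a CSV
manifest, and optionally rendered to 8-bit grayscale PNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

STANDARD_12_LEADS = ["I", "II", "III", "aVR", "aVL", "aVF",
                     "V1", "V2", "V3", "V4", "V5", "V6"]

#: Class vocabulary: healthy control plus eleven infarct localizations.
CLASS_NAMES = [
    "Healthy Control", "Anterior", "Anteriolateral", "Anterioseptal",
    "Anterioseptal Lateral", "Inferior", "Inferiolateral", "Inferioposterior",
    "Inferioposterior Lateral", "Lateral", "Posterior", "Posteriolateral",
]


@dataclass
class ECGRecord:
    """A multi-lead sampled ECG signal in millivolts."""

    signal: np.ndarray          # (n_samples, n_leads)
    fs: float                   # Hz
    lead_names: list[str] = field(default_factory=lambda: list(STANDARD_12_LEADS))
    record_id: str = ""

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (n_samples, n_leads) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.shape[1] != len(self.lead_names):
            raise ValueError(
                f"{self.signal.shape[1]} signal columns but "
                f"{len(self.lead_names)} lead names")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.signal[:, self.lead_names.index(name)]
        except ValueError:
            raise KeyError(f"no lead named {name!r}; have {self.lead_names}") from None


@dataclass
class BeatSegment:
    """One fixed-length window of all leads centered on an R peak."""

    values: np.ndarray          # (segment_length, n_leads)
    r_index_local: int
    r_index_global: int
    label: str | None = None
    source_record: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not (0 <= self.r_index_local < len(self.values)):
            raise ValueError("r_index_local outside the segment")

    @property
    def segment_length(self) -> int:
        return self.values.shape[0]

    @property
    def n_leads(self) -> int:
        return self.values.shape[1]


@dataclass
class DatasetManifest:
    """Index of persisted artifacts: (path, label, split) triples."""

    entries: list[tuple[str, str, str]]
    class_names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))
    created_with_seed: int | None = None

    def __post_init__(self):
        paths = [e[0] for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths must be unique")
        bad = {e[1] for e in self.entries} - set(self.class_names)
        if bad:
            raise ValueError(f"labels outside class vocabulary: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.entries, columns=["path", "label", "split"])
        with open(path, "w") as fh:
            fh.write(f"# seed={self.created_with_seed}\n")
            fh.write(f"# classes={'|'.join(self.class_names)}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        seed, classes = None, list(CLASS_NAMES)
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for ln in lines:
            if ln.startswith("# seed="):
                val = ln.strip().split("=", 1)[1]
                seed = None if val == "None" else int(val)
            elif ln.startswith("# classes="):
                classes = ln.strip().split("=", 1)[1].split("|")
            else:
                body.append(ln)
        import io as _io
        df = pd.read_csv(_io.StringIO("".join(body)), keep_default_na=False)
        entries = [(r.path, r.label, r.split) for r in df.itertuples()]
        return cls(entries=entries, class_names=classes, created_with_seed=seed)


@dataclass
class LabeledImageSet:
    """Stacked image tensor in [0, 1] with integer labels."""

    images: np.ndarray          # (n, H, W, C)
    labels: np.ndarray          # (n,)
    class_names: list[str]

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 4:
            raise ValueError("images must be (n, H, W, C)")
        if len(self.images) != len(self.labels):
            raise ValueError("images/labels length mismatch")
        if self.labels.size and (self.labels.min() < 0
                                 or self.labels.max() >= len(self.class_names)):
            raise ValueError("label outside class range")

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# record readers / writers

def _read_wfdb(path: Path) -> ECGRecord:
    """Minimal WFDB reader: text .hea header plus 16-bit little-endian .dat."""
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    gains, leads = [], []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fmt = tok[1]
        if not fmt.startswith("16"):
            raise ValueError(f"unsupported WFDB signal format {fmt!r} (only 16)")
        gain = 200.0
        if len(tok) > 2:
            g = tok[2].split("/")[0].split("(")[0]
            gain = float(g) if float(g) != 0 else 200.0
        gains.append(gain)
        leads.append(tok[-1] if len(tok) > 8 else f"ch{len(leads)}")
    dat = path.with_suffix(".dat")
    raw = np.fromfile(dat, dtype="<i2")
    sig = raw.reshape(-1, n_sig).astype(float) / np.asarray(gains)
    if n_samples:
        sig = sig[:n_samples]
    return ECGRecord(signal=sig, fs=fs, lead_names=leads, record_id=name)


def read_record(path: str | Path, fs: float | None = None,
                fmt: str = "csv") -> ECGRecord:
    """Read an ECG record from a CSV table or a WFDB-style record pair.

    For CSV, ``fs`` comes from (in priority order) the argument, a YAML
    sidecar ``<stem>.yaml`` with keys ``fs`` and optionally ``leads``.
    Columns named after standard leads are re-ordered into the
    conventional 12-lead order; unnamed columns are taken positionally.
    """
    path = Path(path)
    if fmt == "wfdb":
        return _read_wfdb(path)
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    sidecar = path.with_suffix(".yaml")
    leads_hint = None
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        fs = fs if fs is not None else meta.get("fs")
        leads_hint = meta.get("leads")
    if fs is None:
        raise ValueError("sampling rate required for CSV records "
                         "(argument or YAML sidecar)")
    fs = float(fs)
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")

    df = pd.read_csv(path)
    if df.shape[1] == 0:
        raise ValueError("record has no lead columns")
    # headerless numeric CSV: pandas made the first row the header
    if all(str(c).replace(".", "").replace("-", "").replace("e", "")
           .replace("+", "").isdigit() for c in df.columns):
        df = pd.read_csv(path, header=None)
    try:
        sig = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    names = [str(c) for c in df.columns]
    if leads_hint:
        names = list(leads_hint)
    if set(names) >= set(STANDARD_12_LEADS[:len(names)]) and set(names) <= set(STANDARD_12_LEADS):
        order = [n for n in STANDARD_12_LEADS if n in names]
        sig = sig[:, [names.index(n) for n in order]]
        names = order
    elif all(n.startswith("Unnamed") or n.isdigit() for n in names):
        names = [f"ch{i}" for i in range(len(names))]
    return ECGRecord(signal=sig, fs=fs, lead_names=names, record_id=path.stem)


def write_record(record: ECGRecord, path: str | Path) -> Path:
    """Write a record as CSV plus a YAML sidecar carrying fs and leads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(record.signal, columns=record.lead_names).to_csv(path, index=False)
    sidecar = path.with_suffix(".yaml")
    sidecar.write_text(yaml.safe_dump(
        {"fs": record.fs, "leads": record.lead_names,
         "record_id": record.record_id}))
    return path


# ---------------------------------------------------------------------------
# beats and images

def save_image(img: np.ndarray, path: str | Path) -> None:
    """Save a [0,1] float image (H, W) or (H, W, 1) as 8-bit grayscale PNG."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., 0]
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def load_image(path: str | Path, size: int | None = None) -> np.ndarray:
    """Load a PNG as float (H, W, 1) in [0,1], optionally resized."""
    im = Image.open(path).convert("L")
    if size is not None and im.size != (size, size):
        im = im.resize((size, size), Image.BILINEAR)
    return (np.asarray(im, dtype=float) / 255.0)[..., None]


def write_beats(segments: list[BeatSegment], out_dir: str | Path,
                with_images: bool = False, renderer=None,
                image_size: int = 224, seed: int | None = None) -> DatasetManifest:
    """Persist beat segments (and optionally rendered PNGs) with a manifest.

    One ``.npz`` archive per source record holds that record's beats;
    the manifest lists one row per beat pointing at ``archive#index`` or
    at the rendered PNG when ``with_images`` is set.
    """
    if not segments:
        raise ValueError("no segments to write")
    shapes = {s.values.shape for s in segments}
    if len(shapes) != 1:
        raise ValueError(f"heterogeneous segment shapes: {sorted(shapes)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if renderer is None and with_images:
        from .synthetic import render_beat_image
        renderer = lambda b: render_beat_image(b, size=image_size)  # noqa: E731

    by_record: dict[str, list[BeatSegment]] = {}
    for s in segments:
        by_record.setdefault(s.source_record or "record", []).append(s)

    entries = []
    for rec_id, segs in by_record.items():
        arrays = {f"beat_{i:05d}": s.values for i, s in enumerate(segs)}
        arrays["r_local"] = np.array([s.r_index_local for s in segs])
        arrays["r_global"] = np.array([s.r_index_global for s in segs])
        np.savez_compressed(out_dir / f"{rec_id}.npz", **arrays)
        for i, s in enumerate(segs):
            label = s.label or CLASS_NAMES[0]
            if with_images:
                img_path = out_dir / f"{rec_id}_{i:05d}.png"
                save_image(renderer(s), img_path)
                entries.append((str(img_path), label, "train"))
            else:
                entries.append((f"{out_dir / (rec_id + '.npz')}#beat_{i:05d}",
                                label, "train"))
    manifest = DatasetManifest(entries=entries, created_with_seed=seed)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def load_image_dataset(manifest: DatasetManifest,
                       image_size: int = 224) -> LabeledImageSet:
    """Load every manifest image, resized/normalized, labels as integers."""
    images, labels = [], []
    lut = {c: i for i, c in enumerate(manifest.class_names)}
    for path, label, _split in manifest.entries:
        if label not in lut:
            raise ValueError(f"unknown label {label!r}")
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        images.append(load_image(p, size=image_size))
        labels.append(lut[label])
    return LabeledImageSet(images=np.stack(images), labels=np.array(labels),
                           class_names=list(manifest.class_names))
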