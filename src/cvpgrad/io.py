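"""HDF5/CSV/NIfTI/PNG input-output and configuration handling.

Native layouts (units stored as attributes on every dataset):

* FID dataset: ``/signal`` (complex), ``/slices/positions``, attrs ``dwell``,
  ``noise_sigma``; the acquisition scheme under ``/scheme`` (templates as
  datasets, timing as JSON attributes).
* Field coefficients: ``/d`` (2, T), ``/d_vp``, ``/nuisance``, ``/condition``,
  ``/times``, ``/valid``; CSV export with columns time, dB0, G.
* GSTF: ``/H_real``, ``/H_imag``, ``/freq``; attrs ``dwell_native``,
  ``delay_correction``.
* EPI raw: ``/echoes``, ``/reference_echoes``, ``/k_pe``, attrs ``fov_mm``,
  ``matrix_size``, ``dwell_adc``.

``load_deposited_dataset`` additionally accepts generic MAT v7.3 (HDF5-based)
or older MAT layouts and maps recognizable keys onto the native types.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .errors import FormatError, ParameterError
from .estimation import FieldCoefficients
from .gstf import GSTFSpectrum
from .epi import EPIRawData
from .scheme import AcquisitionScheme, SliceSet, StepDefinition
from .simulate import FIDDataset
from .waveforms import Waveform


# ---------------------------------------------------------------------------
# Waveform / scheme (de)serialization helpers
# ---------------------------------------------------------------------------

def _save_waveform(group: h5py.Group, name: str, wf: Waveform) -> None:
    ds = group.create_dataset(name, data=wf.samples)
    ds.attrs["units"] = "mT/m"
    ds.attrs["dwell_us"] = wf.dwell
    ds.attrs["t0_us"] = wf.t0
    ds.attrs["axis_label"] = wf.axis_label


def _load_waveform(group: h5py.Group, name: str) -> Waveform:
    ds = group[name]
    return Waveform(ds[()], dwell=float(ds.attrs["dwell_us"]),
                    t0=float(ds.attrs["t0_us"]),
                    axis_label=str(ds.attrs["axis_label"]))


def _save_scheme(group: h5py.Group, scheme: AcquisitionScheme) -> None:
    group.attrs["method"] = scheme.method
    group.attrs["readout_start_us"] = scheme.readout_start
    group.attrs["readout_duration_us"] = scheme.readout_duration
    group.create_dataset("prephaser_amplitudes", data=scheme.prephaser_amplitudes)
    _save_waveform(group, "prephaser_shape", scheme.prephaser_shape)
    _save_waveform(group, "test_waveform", scheme.test_waveform)
    _save_waveform(group, "slice_select_waveform", scheme.slice_select_waveform)
    defs = {str(k): {"events": sd.events, "excitation_time": sd.excitation_time}
            for k, sd in scheme.step_definitions.items()}
    group.attrs["step_definitions"] = json.dumps(defs)


def _load_scheme(group: h5py.Group) -> AcquisitionScheme:
    defs_raw = json.loads(group.attrs["step_definitions"])
    defs = {int(k): StepDefinition(
        events={kind: (float(sv[0]), float(sv[1]))
                for kind, sv in v["events"].items()},
        excitation_time=float(v["excitation_time"]))
        for k, v in defs_raw.items()}
    return AcquisitionScheme(
        method=str(group.attrs["method"]),
        prephaser_amplitudes=group["prephaser_amplitudes"][()],
        prephaser_shape=_load_waveform(group, "prephaser_shape"),
        test_waveform=_load_waveform(group, "test_waveform"),
        slice_select_waveform=_load_waveform(group, "slice_select_waveform"),
        step_definitions=defs,
        readout_start=float(group.attrs["readout_start_us"]),
        readout_duration=float(group.attrs["readout_duration_us"]),
    )


# ---------------------------------------------------------------------------
# Native HDF5 writers/readers
# ---------------------------------------------------------------------------

def save_fid(path, data: FIDDataset) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signal", data=data.signal)
        ds.attrs["indexing"] = "(prephasing n, scheme step k, slice m, time t)"
        f.attrs["dwell_us"] = data.dwell
        f.attrs["noise_sigma"] = data.noise_sigma
        g = f.create_group("slices")
        pos = g.create_dataset("positions", data=data.slices.positions)
        pos.attrs["units"] = "mm"
        g.attrs["thickness_mm"] = data.slices.thickness
        _save_scheme(f.create_group("scheme"), data.scheme)


def load_fid(path) -> FIDDataset:
    with h5py.File(path, "r") as f:
        _require(f, ["signal", "slices/positions", "scheme"])
        slices = SliceSet(positions=f["slices/positions"][()],
                          thickness=float(f["slices"].attrs["thickness_mm"]))
        return FIDDataset(signal=f["signal"][()],
                          dwell=float(f.attrs["dwell_us"]),
                          slices=slices, scheme=_load_scheme(f["scheme"]),
                          noise_sigma=float(f.attrs["noise_sigma"]))


def save_field_coefficients(path, fc: FieldCoefficients) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("d", data=np.stack([fc.b0, fc.g]))
        d.attrs["rows"] = "dB0 [Hz], G [mT/m]"
        if fc.d_vp is not None:
            f.create_dataset("d_vp", data=fc.d_vp)
        f.create_dataset("nuisance", data=fc.nuisance)
        f.attrs["nuisance_layout"] = json.dumps(
            {k: [v.start, v.stop] for k, v in fc.nuisance_layout.items()})
        f.create_dataset("condition", data=fc.condition)
        f.create_dataset("valid", data=fc.valid)
        t = f.create_dataset("times", data=fc.times)
        t.attrs["units"] = "us"
        f.attrs["method"] = fc.method
        f.attrs["axis_label"] = fc.axis_label


def load_field_coefficients(path) -> FieldCoefficients:
    with h5py.File(path, "r") as f:
        _require(f, ["d", "nuisance", "condition", "valid", "times"])
        layout = {k: slice(v[0], v[1]) for k, v in
                  json.loads(f.attrs["nuisance_layout"]).items()}
        d = f["d"][()]
        return FieldCoefficients(
            times=f["times"][()], b0=d[0], g=d[1],
            d_vp=f["d_vp"][()] if "d_vp" in f else None,
            nuisance=f["nuisance"][()], nuisance_layout=layout,
            condition=f["condition"][()], valid=f["valid"][()].astype(bool),
            method=str(f.attrs["method"]),
            axis_label=str(f.attrs["axis_label"]))


def field_coefficients_to_csv(path, fc: FieldCoefficients) -> None:
    header = "time_us,dB0_Hz,G_mT_per_m"
    np.savetxt(path, np.column_stack([fc.times, fc.b0, fc.g]),
               delimiter=",", header=header, comments="")


def save_gstf(path, gstf: GSTFSpectrum) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("H_real", data=gstf.H.real)
        f.create_dataset("H_imag", data=gstf.H.imag)
        fr = f.create_dataset("freq", data=gstf.freq)
        fr.attrs["units"] = "kHz"
        f.attrs["dwell_native_us"] = gstf.dwell_native
        f.attrs["delay_correction_us"] = gstf.delay_correction


def load_gstf(path) -> GSTFSpectrum:
    with h5py.File(path, "r") as f:
        _require(f, ["H_real", "H_imag", "freq"])
        return GSTFSpectrum(H=f["H_real"][()] + 1j * f["H_imag"][()],
                            freq=f["freq"][()],
                            dwell_native=float(f.attrs["dwell_native_us"]),
                            delay_correction=float(f.attrs["delay_correction_us"]))


def save_epi_raw(path, raw: EPIRawData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("echoes", data=raw.echoes)
        if raw.reference_echoes is not None:
            f.create_dataset("reference_echoes", data=raw.reference_echoes)
        f.create_dataset("k_pe", data=raw.k_pe_nominal)
        f.attrs["fov_mm"] = raw.fov_mm
        f.attrs["matrix_size"] = raw.matrix_size
        f.attrs["dwell_adc_us"] = raw.dwell_adc


def load_epi_raw(path) -> EPIRawData:
    with h5py.File(path, "r") as f:
        _require(f, ["echoes", "k_pe"])
        return EPIRawData(
            echoes=f["echoes"][()],
            reference_echoes=(f["reference_echoes"][()]
                              if "reference_echoes" in f else None),
            fov_mm=float(f.attrs["fov_mm"]),
            matrix_size=int(f.attrs["matrix_size"]),
            dwell_adc=float(f.attrs["dwell_adc_us"]),
            k_pe_nominal=f["k_pe"][()])


def _require(f: h5py.File, keys: list[str]) -> None:
    missing = [k for k in keys if k not in f]
    if missing:
        found = []
        f.visit(found.append)
        raise FormatError(f"missing dataset key(s) {missing}; file contains "
                          f"{sorted(found)}")


# ---------------------------------------------------------------------------
# Deposited-data adapter (MAT v7.3 / HDF5, read-only)
# ---------------------------------------------------------------------------

_FID_KEYS = ("signal", "fid", "rawdata_fid")
_EPI_KEYS = ("echoes", "kspace", "raw", "rawdata")
_GSTF_KEYS = ("H", "gstf", "GIRF", "girf")


def load_deposited_dataset(path):
    """Map an externally deposited MAT v7.3 / HDF5 file onto native types.

    Key-pattern based: complex FID arrays -> :class:`FIDDataset` is not
    attempted (scheme metadata cannot be reconstructed); GSTF-like and EPI
    raw-like layouts are mapped; unrecognized layouts raise a descriptive
    error listing the keys found.  Unknown fields are returned alongside the
    mapped object as an opaque metadata dict.
    """
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError:
        return _load_deposited_mat_legacy(path)
    with f:
        keys = []
        f.visit(keys.append)
        flat = {k.split("/")[-1]: k for k in keys if isinstance(f[k], h5py.Dataset)}

        for name in _GSTF_KEYS:
            if name in flat:
                h = _as_complex(f[flat[name]][()]).squeeze()
                freq_key = next((flat[k] for k in ("freq", "f", "frequency")
                                 if k in flat), None)
                if freq_key is None:
                    raise FormatError(
                        f"found GSTF-like key {name!r} but no frequency axis; "
                        f"file contains {sorted(keys)}")
                freq = np.asarray(f[freq_key][()], dtype=float).squeeze()
                if freq.max() > 1e4:  # Hz axis -> kHz
                    freq = freq * 1e-3
                dwell = 1e6 / (2.0 * abs(freq).max() * 1e3)
                meta = {k: None for k in flat if k not in (name, "freq", "f",
                                                           "frequency")}
                return GSTFSpectrum(H=h, freq=freq, dwell_native=dwell), meta

        for name in _EPI_KEYS:
            if name in flat:
                echoes = _as_complex(f[flat[name]][()])
                if echoes.ndim == 2:
                    echoes = echoes[:, :, None]
                n_lines = echoes.shape[0]
                refs = None
                for rk in ("reference_echoes", "refs", "navigator"):
                    if rk in flat:
                        refs = _as_complex(f[flat[rk]][()])
                fov = float(np.asarray(f[flat["fov_mm"]][()]).squeeze()) \
                    if "fov_mm" in flat else float("nan")
                dk = 1.0 / (fov * 1e-3) if np.isfinite(fov) else 1.0
                k_pe = (np.arange(n_lines) - n_lines // 2) * dk
                meta = {k: None for k in flat}
                return EPIRawData(echoes=echoes, reference_echoes=refs,
                                  fov_mm=fov, matrix_size=echoes.shape[1],
                                  dwell_adc=float("nan"), k_pe_nominal=k_pe), meta

        if "signal" in flat and "scheme" in f:
            return load_fid(path), {}

        raise FormatError("unrecognized layout; file contains keys "
                          f"{sorted(keys)}")


def _as_complex(arr: np.ndarray) -> np.ndarray:
    """MAT v7.3 stores complex data as structured (real, imag) arrays."""
    arr = np.asarray(arr)
    if arr.dtype.names and {"real", "imag"} <= set(arr.dtype.names):
        return arr["real"] + 1j * arr["imag"]
    return arr.astype(complex)


def _load_deposited_mat_legacy(path: Path):
    from scipy.io import loadmat

    try:
        contents = loadmat(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with key context
        raise FormatError(f"cannot read {path} as HDF5 or MAT: {exc}") from exc
    keys = [k for k in contents if not k.startswith("__")]
    raise FormatError(f"legacy MAT layout not supported; file contains keys "
                      f"{sorted(keys)}")


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_nifti(path, image: np.ndarray, voxel_size_mm: float = 1.0) -> None:
    import nibabel as nib

    affine = np.diag([voxel_size_mm, voxel_size_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), affine), path)


def write_png(path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    img = np.abs(np.asarray(image, dtype=float))
    peak = img.max() or 1.0
    iio.imwrite(path, (255 * img / peak).astype(np.uint8))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_TOP_LEVEL_KEYS = {"seed", "model", "scheme", "slices", "simulate", "estimate",
                   "gstf", "recon", "output"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Reject unknown keys and configs whose stochastic stages lack a seed."""
    if not isinstance(cfg, dict):
        raise ParameterError("config must be a mapping")
    unknown = set(cfg) - _TOP_LEVEL_KEYS
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    sim = cfg.get("simulate", {})
    if sim.get("noise_sigma", 0.0) > 0 and cfg.get("seed") is None:
        raise ParameterError("noisy simulation requires an explicit seed")
    recon = cfg.get("recon", {})
    if recon.get("noise_sigma", 0.0) > 0 and cfg.get("seed") is None:
        raise ParameterError("noisy EPI simulation requires an explicit seed")
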