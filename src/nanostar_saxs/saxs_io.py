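"""File formats: 3-column SAXS ASCII curves, batch manifests, fit reports.

The native curve dialect is 3+ columns of (q [Å^-1], I [cm^-1], sigma
[cm^-1]) with ``#`` comment headers carrying ``key: value`` metadata.
q given in nm^-1 must be declared in the header (``units_q: 1/nm``) and is
converted on read; intensities are absolute (cm^-1) throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import yaml

from .fitting import FitResult, SAXSCurve

__all__ = [
    "CurveFileDialect",
    "read_saxs_curve",
    "write_saxs_curve",
    "write_batch",
    "read_batch",
    "write_report",
    "read_report",
    "CurveFormatError",
]


class CurveFormatError(ValueError):
    pass


@dataclass(frozen=True)
class CurveFileDialect:
    comment: str = "#"
    columns: tuple = ("q", "I", "sigma")
    units_q: str = "1/A"  # or '1/nm'


_META_FIELDS = {"T": float, "c": float, "I_S": float, "ramp": str, "label": str}


def read_saxs_curve(path, dialect: CurveFileDialect | None = None, **overrides) -> SAXSCurve:
    """Read a curve file; non-finite rows are dropped (count reported).

    Header comments of the form ``# key: value`` populate the curve
    metadata (T, c, I_S, ramp, label, units_q); keyword overrides win.
    """
    dia = dialect or CurveFileDialect()
    meta: dict = {}
    rows = []
    n_dropped = 0
    with open(path) as fh:
        for ln_no, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(dia.comment):
                body = s.lstrip(dia.comment).strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = s.split()
            if len(parts) < 3:
                if len(parts) == 2:
                    raise CurveFormatError(
                        f"{path}:{ln_no}: only 2 columns; a sigma column is "
                        f"required (no assumed-noise mode is applied silently)"
                    )
                raise CurveFormatError(
                    f"{path}:{ln_no}: expected >= 3 columns, got {len(parts)}"
                )
            try:
                vals = [float(parts[i]) for i in range(3)]
            except ValueError as exc:
                raise CurveFormatError(f"{path}:{ln_no}: {exc}") from None
            if not all(np.isfinite(vals)):
                n_dropped += 1
                continue
            rows.append((ln_no, vals))
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")

    data = np.array([v for _, v in rows])
    order = {name: i for i, name in enumerate(dia.columns)}
    q = data[:, order["q"]]
    I = data[:, order["I"]]
    sigma = data[:, order["sigma"]]

    units_q = meta.get("units_q", dia.units_q)
    if units_q in ("1/nm", "nm^-1"):
        q = q / 10.0
    elif units_q not in ("1/A", "A^-1", "1/Angstrom"):
        raise CurveFormatError(f"{path}: unknown q unit {units_q!r}")

    bad = np.flatnonzero(np.diff(q) <= 0)
    if bad.size:
        ln = rows[bad[0] + 1][0]
        raise CurveFormatError(f"{path}:{ln}: q is not strictly increasing")

    kwargs = {}
    for key, conv in _META_FIELDS.items():
        if key in overrides:
            kwargs[key] = overrides[key]
        elif key in meta:
            kwargs[key] = conv(meta[key])
    kwargs.setdefault("T", 298.15)
    kwargs.setdefault("c", 0.0)
    kwargs.setdefault("I_S", 0.0)
    curve = SAXSCurve(q=q, I=I, sigma=sigma, **kwargs)
    curve.n_dropped = n_dropped  # type: ignore[attr-defined]
    return curve


def write_saxs_curve(curve: SAXSCurve, path, seed=None,
                     dialect: CurveFileDialect | None = None) -> None:
    dia = dialect or CurveFileDialect()
    with open(path, "w") as fh:
        fh.write(f"{dia.comment} columns: q[1/A] I[1/cm] sigma[1/cm]\n")
        fh.write(f"{dia.comment} T: {curve.T}\n")
        fh.write(f"{dia.comment} c: {curve.c}\n")
        fh.write(f"{dia.comment} I_S: {curve.I_S}\n")
        fh.write(f"{dia.comment} ramp: {curve.ramp}\n")
        if curve.label:
            fh.write(f"{dia.comment} label: {curve.label}\n")
        if seed is not None:
            fh.write(f"{dia.comment} seed: {seed}\n")
        for q, I, s in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{q:.8e} {I:.8e} {s:.8e}\n")


def write_batch(curves, directory, manifest_path, seed=None) -> None:
    """Write curve files plus a YAML manifest of per-curve conditions."""
    import os

    entries = []
    for i, curve in enumerate(curves):
        name = f"curve_{i:02d}.dat"
        write_saxs_curve(curve, os.path.join(directory, name), seed=seed)
        entries.append(
            {
                "file": name,
                "T": float(curve.T),
                "c": float(curve.c),
                "I_S": float(curve.I_S),
                "ramp": curve.ramp,
                "label": curve.label,
            }
        )
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"seed": seed, "curves": entries}, fh, sort_keys=False)


def read_batch(manifest_path):
    """Read a batch manifest and its curve files (order preserved)."""
    import os

    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(manifest_path))
    curves = []
    for entry in manifest["curves"]:
        curves.append(
            read_saxs_curve(
                os.path.join(base, entry["file"]),
                T=float(entry["T"]),
                c=float(entry["c"]),
                I_S=float(entry["I_S"]),
                ramp=entry.get("ramp", "heating"),
                label=entry.get("label", ""),
            )
        )
    return curves


def write_report(result: FitResult, path, extra=None) -> None:
    """Serialize a fit result as a JSON report (re-readable)."""
    from . import __version__

    payload = {
        "version": __version__,
        "seed": result.seed,
        "converged": result.converged,
        "merit": result.merit,
        "chi2_bar": result.chi2_bar,
        "L": result.L,
        "alpha_reg": result.alpha_reg,
        "common": {
            "dh0": result.dh0,
            "dh0_err": result.dh0_err,
            "alpha_h": result.alpha_h,
            "alpha_h_err": result.alpha_h_err,
        },
        "per_curve": [
            {
                "R": row[0],
                "J": row[1],
                "d": row[2],
                "R_err": err[0],
                "J_err": err[1],
                "d_err": err[2],
            }
            for row, err in zip(result.per_curve.tolist(), result.per_curve_err.tolist())
        ],
        "message": result.message,
    }
    if extra:
        payload["extra"] = extra
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
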