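"""IAEA phase-space file dialect (``.IAEAheader`` + ``.IAEAphsp``).

Implements the fixed-record binary layout used for linac phase spaces:

* one signed byte of particle type (1 photon, 2 electron, 3 positron); the
  **sign of the type byte carries the sign of w**, which is otherwise
  reconstructed from the stored ``u, v`` via normalization;
* single-precision floats for energy, x, y, (z unless header-constant),
  u, v, weight; the **sign of the stored energy flags a new history**
  (negative energy = first particle of a new primary history);
* optional extra floats / extra longs per record, preserved opaquely.

The text header is a ``$KEY:`` block file carrying record structure,
constants for non-stored coordinates, and particle/history totals.  Only the
keys needed for interoperability are written; unknown keys are ignored on
read.  The native (lossless, float64) container lives in
:mod:`fajtrace.phasespace`; IAEA is the import/export format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .phasespace import PhaseSpaceStore

_FLOAT_FIELDS = ("x", "y", "z", "u", "v", "weight")  # order within a record


class IAEAFormatError(ValueError):
    """Malformed IAEA header; the message names the offending key."""


def _parse_header(text: str) -> dict:
    """Split a ``$KEY:`` block file into {key: [lines]}."""
    sections: dict[str, list[str]] = {}
    key = None
    for line in text.splitlines():
        if line.startswith("$") and line.rstrip().endswith(":"):
            key = line.strip()[1:-1]
            sections[key] = []
        elif key is not None:
            stripped = line.split("//")[0].strip()
            if stripped:
                sections[key].append(stripped)
    return sections


def _require(sections: dict, key: str) -> list[str]:
    if key not in sections:
        raise IAEAFormatError(f"header missing required key ${key}:")
    return sections[key]


def read_iaea(header_path, record_path=None) -> PhaseSpaceStore:
    """Read an IAEA phase-space file pair into a :class:`PhaseSpaceStore`.

    ``record_path`` defaults to the header path with the ``.IAEAphsp``
    extension.
    """
    header_path = Path(header_path)
    if record_path is None:
        record_path = header_path.with_suffix(".IAEAphsp")
    sections = _parse_header(header_path.read_text())

    try:
        n_particles = int(_require(sections, "PARTICLES")[0])
        n_orig = float(_require(sections, "ORIG_HISTORIES")[0])
        flags = [int(v.split()[0]) for v in _require(sections, "RECORD_CONTENTS")]
    except (ValueError, IndexError) as e:
        raise IAEAFormatError(f"unparseable header value: {e}") from e
    if len(flags) < 9:
        raise IAEAFormatError("header key $RECORD_CONTENTS: needs 9 flag lines")
    stored = dict(zip(("x", "y", "z", "u", "v", "w", "weight"), flags[:7]))
    n_extra_float, n_extra_long = flags[7], flags[8]
    if stored["w"]:
        raise IAEAFormatError(
            "header key $RECORD_CONTENTS: explicit w storage not supported "
            "(w is reconstructed from u, v)")

    constants = {}
    const_lines = sections.get("RECORD_CONSTANT", [])
    const_fields = [f for f in _FLOAT_FIELDS if f != "w" and not stored[f]]
    if len(const_lines) < len(const_fields):
        raise IAEAFormatError(
            "header key $RECORD_CONSTANT: expected "
            f"{len(const_fields)} values, got {len(const_lines)}")
    for f, v in zip(const_fields, const_lines):
        constants[f] = float(v.split()[0])

    n_float = sum(1 for f in ("x", "y", "z", "u", "v", "weight") if stored[f]) + 1
    record_length = 1 + 4 * (n_float + n_extra_float) + 4 * n_extra_long
    if "RECORD_LENGTH" in sections:
        declared = int(sections["RECORD_LENGTH"][0])
        if declared != record_length:
            raise IAEAFormatError(
                f"header key $RECORD_LENGTH: declared {declared} but record "
                f"structure implies {record_length}")

    raw = np.fromfile(record_path, dtype=np.uint8)
    if raw.size != n_particles * record_length:
        offset = (raw.size // record_length) * record_length
        raise IOError(
            f"truncated record file {record_path}: {raw.size} bytes, expected "
            f"{n_particles * record_length}; first bad byte offset {offset}")
    rec = raw.reshape(n_particles, record_length) if n_particles else raw.reshape(0, record_length)

    type_signed = rec[:, :1].view(np.int8)[:, 0] if n_particles else np.zeros(0, np.int8)
    floats = rec[:, 1:1 + 4 * (n_float + n_extra_float)].view("<f4") if n_particles \
        else np.zeros((0, n_float + n_extra_float), "<f4")
    cols = {}
    i = 0
    energy_signed = floats[:, i].astype(np.float64); i += 1
    for f in ("x", "y", "z", "u", "v", "weight"):
        if stored[f]:
            cols[f] = floats[:, i].astype(np.float64); i += 1
        else:
            cols[f] = np.full(n_particles, constants[f])
    extra_floats = floats[:, i:i + n_extra_float].copy() if n_extra_float else None
    extra_longs = (rec[:, record_length - 4 * n_extra_long:].view("<i4").copy()
                   if n_extra_long else None)

    kind = np.abs(type_signed)
    w_sign = np.where(type_signed < 0, -1.0, 1.0)
    new_history = energy_signed < 0
    energy = np.abs(energy_signed)
    w = w_sign * np.sqrt(np.clip(1.0 - cols["u"] ** 2 - cols["v"] ** 2, 0.0, None))

    return PhaseSpaceStore(
        kind, energy, cols["x"], cols["y"], cols["z"], cols["u"], cols["v"], w,
        cols["weight"], new_history,
        z_plane=constants.get("z"), n_original_histories=n_orig,
        extra_floats=extra_floats, extra_longs=extra_longs)


def write_iaea(store: PhaseSpaceStore, header_path, record_path=None,
               title: str = "fajtrace phase space") -> None:
    """Write a store as an IAEA header/record pair (single precision)."""
    header_path = Path(header_path)
    if record_path is None:
        record_path = header_path.with_suffix(".IAEAphsp")
    n = len(store)
    z_const = n == 0 or bool(np.all(np.abs(store.z - store.z_plane) <= 1e-4))

    ef = store.extra_floats
    el = store.extra_longs
    n_extra_float = 0 if ef is None else ef.shape[1]
    n_extra_long = 0 if el is None else el.shape[1]
    n_float = 6 if z_const else 7  # energy,x,y,(z),u,v,weight
    record_length = 1 + 4 * (n_float + n_extra_float) + 4 * n_extra_long

    rec = np.zeros((n, record_length), dtype=np.uint8)
    if n:
        type_signed = (store.kind.astype(np.int8) *
                       np.where(store.w < 0, -1, 1).astype(np.int8))
        rec[:, :1] = type_signed.view(np.uint8)[:, None]
        fl = np.empty((n, n_float + n_extra_float), dtype="<f4")
        i = 0
        fl[:, i] = np.where(store.new_history, -store.energy, store.energy); i += 1
        for fname in ("x", "y") + (() if z_const else ("z",)) + ("u", "v", "weight"):
            fl[:, i] = getattr(store, fname); i += 1
        if n_extra_float:
            fl[:, i:] = ef
        rec[:, 1:1 + 4 * fl.shape[1]] = fl.view(np.uint8).reshape(n, -1)
        if n_extra_long:
            rec[:, record_length - 4 * n_extra_long:] = (
                el.astype("<i4").view(np.uint8).reshape(n, -1))

    counts = store.counts_by_kind
    flags = {"x": 1, "y": 1, "z": 0 if z_const else 1, "u": 1, "v": 1,
             "w": 0, "weight": 1}
    lines = [
        "$IAEA_INDEX:", "0", "",
        "$TITLE:", title, "",
        "$FILE_TYPE:", "0", "",
        "$CHECKSUM:", str(n * record_length), "",
        "$RECORD_LENGTH:", str(record_length), "",
        "$BYTE_ORDER:", "1234", "",
        "$RECORD_CONTENTS:",
    ]
    for fname in ("x", "y", "z", "u", "v", "w", "weight"):
        lines.append(f"    {flags[fname]}     // {fname.upper()} is stored ?")
    lines.append(f"    {n_extra_float}     // extra floats stored ?")
    lines.append(f"    {n_extra_long}     // extra longs stored ?")
    lines.append("")
    if z_const:
        lines += ["$RECORD_CONSTANT:", f"    {store.z_plane:.6f}     // constant Z", ""]
    lines += [
        "$ORIG_HISTORIES:", str(int(round(store.n_original_histories))), "",
        "$PARTICLES:", str(n), "",
        "$PHOTONS:", str(counts["photon"]), "",
        "$ELECTRONS:", str(counts["electron"]), "",
        "$POSITRONS:", str(counts["positron"]), "",
    ]
    header_path.write_text("\n".join(lines) + "\n")
    rec.tofile(record_path)
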