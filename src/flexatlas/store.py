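"""On-disk layout for an atlas directory.

An atlas directory holds ``AO.json`` (ontology, plain nested dialect),
``AV.nrrd`` or ``AV.nii.gz`` (annotation volume), ``meta.json`` (voxel
size and left–right axis declaration), ``sizes.csv`` and
``provenance.log``.
"""

from __future__ import annotations

import json
from pathlib import Path

from .base import FAA
from .ontology import load_ontology, save_ontology
from .volume import label_size_table, read_volume, write_volume

__all__ = ["save_faa", "load_faa"]


def save_faa(faa: FAA, out_dir, volume_format: str = "nrrd") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "AO.json").write_text(save_ontology(faa.ontology))
    vol_name = "AV.nrrd" if volume_format == "nrrd" else "AV.nii.gz"
    write_volume(faa.volume, out / vol_name, volume_format)
    meta = {
        "voxel_size_um": faa.volume.voxel_size_um,
        "lr_axis": faa.volume.lr_axis,
        "left_is_low": faa.volume.left_is_low,
        "volume_file": vol_name,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    label_size_table(faa.volume, faa.ontology).to_csv(out / "sizes.csv", index=False)
    (out / "provenance.log").write_text("\n".join(faa.provenance) + "\n")
    return out


def load_faa(faa_dir) -> FAA:
    d = Path(faa_dir)
    onto = load_ontology((d / "AO.json").read_text())
    meta = json.loads((d / "meta.json").read_text())
    vol = read_volume(
        d / meta["volume_file"],
        voxel_size_um=meta["voxel_size_um"],
        lr_axis=meta["lr_axis"],
        left_is_low=meta["left_is_low"],
    )
    provenance = []
    log = d / "provenance.log"
    if log.exists():
        provenance = [ln for ln in log.read_text().splitlines() if ln]
    return FAA(onto, vol, provenance)
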