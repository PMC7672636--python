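"""End-to-end orchestration: label stack or phantom in, report bundle out.

``run_all`` drives the full measurement suite and writes six CSV reports
plus a ``run.json`` manifest into the output directory.  Every CSV carries
provenance columns (interface mode, area method, mitochondria connectivity)
and the whole bundle is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import (SamplingScheme, brm_thickness, combined_height,
                       microvillus_geometry, rpe_height)
from .interfaces import cell_contact_areas
from .model import (CompartmentKind, LabelVolume, VoxelSpacing,
                    read_label_stack)
from .morphometry import (cell_summary, mitochondria_stats, morphometry_table)
from .phantom import PhantomSpec, generate_phantom

__all__ = ["RunConfig", "SummaryRow", "summarise", "run_all",
           "phantom_spec_from_dict", "phantom_spec_to_dict"]

logger = logging.getLogger(__name__)


@dataclass
class SummaryRow:
    quantity: str
    n: int
    mean: float
    sd: float
    units: str
    single_sample: bool = False

    @property
    def formatted(self) -> str:
        """Paper-style "mean units ± SD" string."""
        return f"{self.mean:.4g} {self.units} ± {self.sd:.4g} SD"


def summarise(samples: Sequence[float], units: str = "",
              quantity: str = "") -> SummaryRow:
    """Mean ± sample SD (n−1 denominator) of a list of measurements.

    A single sample yields SD 0 with the ``single_sample`` flag set.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.size == 0:
        raise ValueError("summarise needs at least one sample")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryRow(quantity=quantity, n=int(arr.size),
                      mean=float(arr.mean()), sd=sd, units=units,
                      single_sample=arr.size == 1)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``stack`` (with ``table``) or ``phantom_spec`` must be
    given.  ``spacing_nm`` is (dz, dy, dx); it may be omitted when the label
    table JSON or the phantom spec carries the spacing.
    """

    stack: Optional[str] = None
    table: Optional[str] = None
    phantom_spec: Optional[PhantomSpec] = None
    spacing_nm: Optional[Sequence[float]] = None
    slice_interval: int = 50
    measurements_per_slice: int = 10
    interface_mode: str = "corrected"
    area_method: str = "voxel_face"
    mito_connectivity: int = 26
    out_dir: str = "rpe3d_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.stack is None) == (self.phantom_spec is None):
            raise ValueError("exactly one of stack or phantom_spec must be "
                             "supplied")
        if self.stack is not None and self.table is None:
            raise ValueError("a label table is required with a stack")
        if self.interface_mode not in ("fidelity", "corrected"):
            raise ValueError("interface_mode must be fidelity or corrected")
        if self.mito_connectivity not in (6, 18, 26):
            raise ValueError("mito_connectivity must be 6, 18 or 26")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        spec = doc.pop("phantom_spec", None)
        cfg = cls(**{**doc, **{k: v for k, v in overrides.items()
                               if v is not None}})
        if spec is not None:
            cfg.phantom_spec = phantom_spec_from_dict(spec)
        return cfg


def phantom_spec_from_dict(d: Dict) -> PhantomSpec:
    d = dict(d)
    spacing = d.pop("spacing_nm", None)
    kwargs = {}
    for f in dataclasses.fields(PhantomSpec):
        if f.name in d:
            v = d.pop(f.name)
            if f.name in ("nucleus_semiaxes", "mito_semiaxes"):
                v = tuple(v)
            kwargs[f.name] = v
    if d:
        raise ValueError(f"unknown phantom spec fields: {sorted(d)}")
    if spacing is not None:
        dz, dy, dx = spacing
        kwargs["spacing"] = VoxelSpacing(dx=dx, dy=dy, dz=dz)
    return PhantomSpec(**kwargs)


def phantom_spec_to_dict(spec: PhantomSpec) -> Dict:
    d = dataclasses.asdict(spec)
    sp = d.pop("spacing")
    d["spacing_nm"] = [sp["dz"], sp["dy"], sp["dx"]]
    d["nucleus_semiaxes"] = list(d["nucleus_semiaxes"])
    d["mito_semiaxes"] = list(d["mito_semiaxes"])
    if not np.isscalar(d["nuclei_per_cell"]):
        d["nuclei_per_cell"] = list(d["nuclei_per_cell"])
    return d


def _load_volume(config: RunConfig) -> LabelVolume:
    if config.phantom_spec is not None:
        vol, _truth = generate_phantom(config.phantom_spec)
        return vol
    spacing = None
    if config.spacing_nm is not None:
        dz, dy, dx = config.spacing_nm
        spacing = VoxelSpacing(dx=dx, dy=dy, dz=dz)
    return read_label_stack(config.stack, spacing=spacing,
                            table_path=config.table)


def _provenance(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["mode"] = config.interface_mode
    df["area_method"] = config.area_method
    df["connectivity"] = config.mito_connectivity
    return df


def run_all(config: RunConfig) -> Dict[str, Path]:
    """Run the complete measurement suite and write the report bundle.

    Outputs (in ``config.out_dir``): morpho.csv, mito.csv, interfaces.csv,
    contacts.csv, geometry.csv, summary.csv, run.json.  Any stage failure
    aborts the run, removes partial outputs, and re-raises.
    """
    config.validate()
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.log_level.upper(), 20))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, Path] = {}
    timings: Dict[str, float] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        vol = _load_volume(config)
        timings[stage] = time.perf_counter() - t0
        cells = vol.table.cell_ids()
        scheme = SamplingScheme(config.slice_interval,
                                config.measurements_per_slice, config.seed)

        stage = "morphometry"
        t0 = time.perf_counter()
        morpho = _provenance(morphometry_table(vol), config)
        summaries = {cid: cell_summary(vol, cid) for cid in cells}
        cell_rows = pd.DataFrame([
            {
                "cell_id": cid,
                "n_nuclei": s.n_nuclei,
                "cytoplasm_volume_um3": s.cytoplasm_volume_um3,
                "nucleus_excluded_volume_um3": s.nucleus_excluded_volume_um3,
                "microvilli_volume_um3": s.microvilli_volume_um3,
                "infold_volume_um3": s.infold_volume_um3,
                "photoreceptors_supported": s.photoreceptors_supported,
                "photoreceptor_density_per_um3": s.photoreceptor_density_2sf,
                "microvilli_contact_area_um2": s.microvilli_contact_area_um2,
            }
            for cid, s in summaries.items()
        ])
        morpho = pd.concat(
            [morpho, _provenance(cell_rows, config)], ignore_index=True)
        outputs["morpho"] = out_dir / "morpho.csv"
        morpho.to_csv(outputs["morpho"], index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "mitochondria"
        t0 = time.perf_counter()
        mito_rows = []
        for cid in cells:
            st = mitochondria_stats(vol, cid,
                                    connectivity=config.mito_connectivity)
            mito_rows.append({
                "cell_id": cid,
                "count": st.count,
                "mean_volume_nm3": st.mean_volume_nm3,
                "sd_volume_nm3": st.sd_volume_nm3,
                "min_volume_nm3": st.min_volume_nm3,
                "total_volume_nm3": st.total_volume_nm3,
                "basal_fraction": st.basal_fraction,
            })
        outputs["mito"] = out_dir / "mito.csv"
        _provenance(pd.DataFrame(mito_rows), config).to_csv(
            outputs["mito"], index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "interfaces"
        t0 = time.perf_counter()
        if len(cells) >= 2:
            contacts, c_mean, c_sd = cell_contact_areas(
                vol, mode=config.interface_mode)
        else:
            contacts = pd.DataFrame(columns=["cell_a", "cell_b", "mode",
                                             "n_slices", "total_area_um2",
                                             "mean_slice_area_um2",
                                             "face_area_um2"])
            c_mean = c_sd = float("nan")
        iface = contacts.copy()
        iface.insert(2, "label_a", [
            ";".join(map(str, vol.table.labels_for(a, CompartmentKind.CELL_BODY)))
            for a in iface["cell_a"]])
        iface.insert(3, "label_b", [
            ";".join(map(str, vol.table.labels_for(b, CompartmentKind.CELL_BODY)))
            for b in iface["cell_b"]])
        outputs["interfaces"] = out_dir / "interfaces.csv"
        _provenance(iface, config).to_csv(outputs["interfaces"], index=False)
        outputs["contacts"] = out_dir / "contacts.csv"
        _provenance(contacts, config).to_csv(outputs["contacts"], index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "geometry"
        t0 = time.perf_counter()
        geo_rows: List[dict] = []
        mv_lengths, mv_angles, body_heights, combined = [], [], [], []
        for cid in cells:
            try:
                lset, aset = microvillus_geometry(vol, cid, scheme)
            except ValueError:
                continue
            body, comb = rpe_height(vol, cid, scheme,
                                    microvillus_length_mean_um=lset.mean)
            for s in (lset, aset, body):
                geo_rows.append({"quantity": s.quantity, "cell_id": cid,
                                 "n": s.n, "mean": s.mean, "sd": s.sd,
                                 "units": s.units})
            geo_rows.append({"quantity": "rpe_combined_height", "cell_id": cid,
                             "n": body.n, "mean": comb, "sd": float("nan"),
                             "units": "um"})
            mv_lengths.extend(lset.samples)
            mv_angles.extend(aset.samples)
            body_heights.extend(body.samples)
            combined.append(comb)
        try:
            brm = brm_thickness(vol, scheme)
            geo_rows.append({"quantity": brm.quantity, "cell_id": "all",
                             "n": brm.n, "mean": brm.mean, "sd": brm.sd,
                             "units": brm.units})
        except ValueError:
            brm = None
        outputs["geometry"] = out_dir / "geometry.csv"
        _provenance(pd.DataFrame(
            geo_rows, columns=["quantity", "cell_id", "n", "mean", "sd",
                               "units"]), config).to_csv(
            outputs["geometry"], index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "summary"
        t0 = time.perf_counter()
        summary_rows: List[SummaryRow] = []

        def add(samples, units, quantity):
            if len(samples):
                summary_rows.append(summarise(samples, units, quantity))

        add(mv_lengths, "um", "microvillus_length")
        add(mv_angles, "deg", "microvillus_angle")
        add(body_heights, "um", "rpe_body_height")
        add(combined, "um", "rpe_combined_height")
        if brm is not None:
            add(list(brm.samples), "nm", "brm_thickness")
        if len(contacts):
            add(list(contacts["total_area_um2"]), "um2", "cell_contact_area")
        add([s.cytoplasm_volume_um3 for s in summaries.values()], "um3",
            "cytoplasm_volume")
        add([s.nucleus_excluded_volume_um3 for s in summaries.values()], "um3",
            "nucleus_excluded_volume")
        add([float(s.photoreceptors_supported) for s in summaries.values()],
            "count", "photoreceptors_supported")
        add([r["count"] for r in mito_rows], "count", "mitochondria_per_cell")
        summary = pd.DataFrame([
            {"quantity": r.quantity, "n": r.n, "mean": r.mean, "sd": r.sd,
             "units": r.units, "formatted": r.formatted,
             "single_sample": r.single_sample}
            for r in summary_rows
        ])
        outputs["summary"] = out_dir / "summary.csv"
        _provenance(summary, config).to_csv(outputs["summary"], index=False)
        timings[stage] = time.perf_counter() - t0

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": {
                **{k: v for k, v in dataclasses.asdict(config).items()
                   if k != "phantom_spec"},
                "phantom_spec": (phantom_spec_to_dict(config.phantom_spec)
                                 if config.phantom_spec is not None else None),
            },
            "stage_wall_times_s": {k: round(v, 3) for k, v in timings.items()},
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        outputs["run"] = out_dir / "run.json"
        outputs["run"].write_text(json.dumps(manifest, indent=1))
    except Exception:
        logger.error("pipeline stage %r failed; removing partial outputs",
                     stage)
        for p in outputs.values():
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise
    return outputs
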