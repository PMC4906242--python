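"""Hierarchical experiment simulator: preparations -> fields -> boutons.

Field- and bouton-level lognormal multipliers on the kinetic rates generate
the intra-field correlation that the clustered statistics must account for;
group effects multiply the exocytosis rate only.  Every output is a pure
function of the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, model_validator

from ..protocol import StimProtocol
from .kinetics import KineticParams, PoolTraces, simulate_pools
from .render import RenderedField, RenderParams, render_movie

__all__ = ["HierarchyDesign", "SimulatedField", "SimulatedExperiment", "simulate_experiment"]


class HierarchyDesign(BaseModel):
    n_preps: int = 3
    fields_per_prep: int = 6
    boutons_per_field: int = 50
    sigma_field: float = 0.2  # SD of lognormal field multiplier on rates
    sigma_bouton: float = 0.2  # SD of lognormal bouton multiplier
    group_assignment: dict[str, str] | None = None  # field_id -> group
    group_effects: dict[str, float] = {"ctrl": 1.0}
    seed: int = 0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "HierarchyDesign":
        if min(self.n_preps, self.fields_per_prep, self.boutons_per_field) < 1:
            raise ValueError("counts must be >= 1")
        if self.sigma_field < 0 or self.sigma_bouton < 0:
            raise ValueError("sigma values must be >= 0")
        if self.group_assignment is not None:
            unknown = set(self.group_assignment.values()) - set(self.group_effects)
            if unknown:
                raise ValueError(f"groups without an effect entry: {unknown}")
        return self

    def field_ids(self) -> list[tuple[str, str]]:
        """(prep_id, field_id) pairs in deterministic order."""
        return [
            (f"prep{p}", f"prep{p}_field{f}")
            for p in range(self.n_preps)
            for f in range(self.fields_per_prep)
        ]

    def group_of(self, field_index: int, field_id: str) -> str:
        if self.group_assignment is not None:
            return self.group_assignment[field_id]
        groups = sorted(self.group_effects)
        return groups[field_index % len(groups)]


@dataclass
class SimulatedField:
    prep_id: str
    field_id: str
    group: str
    rendered: RenderedField | None
    truth: pd.DataFrame  # one row per bouton
    pools: list[PoolTraces]


@dataclass
class SimulatedExperiment:
    fields: list[SimulatedField]
    truth: pd.DataFrame  # concatenated bouton-level ground truth
    manifest: pd.DataFrame
    protocol: StimProtocol


def simulate_experiment(
    design: HierarchyDesign,
    kinetics: KineticParams,
    render: RenderParams | None,
    protocol: StimProtocol,
    out_dir: str | Path | None = None,
    quantize: bool = True,
) -> SimulatedExperiment:
    """Simulate one movie per field with known per-bouton kinetics.

    ``render=None`` skips movie rendering (ground-truth kinetics and pool
    traces only).  When ``out_dir`` is given, writes one multi-page TIFF per
    field plus ``manifest.csv`` and ``ground_truth.csv`` linking files to the
    hierarchy.
    """
    rng = np.random.default_rng(design.seed)
    pairs = design.field_ids()
    if len(set(fid for _, fid in pairs)) != len(pairs):
        raise ValueError("duplicate field ids")

    fields: list[SimulatedField] = []
    truth_rows = []
    manifest_rows = []
    for fi, (prep_id, field_id) in enumerate(pairs):
        group = design.group_of(fi, field_id)
        g_mult = design.group_effects[group]
        f_mult = float(np.exp(rng.normal(0.0, design.sigma_field)))
        b_mults = np.exp(rng.normal(0.0, design.sigma_bouton, size=design.boutons_per_field))

        pools = []
        traces = np.empty((design.boutons_per_field, protocol.n_frames))
        k_exos = np.empty(design.boutons_per_field)
        k_endos = np.empty(design.boutons_per_field)
        for b in range(design.boutons_per_field):
            kp = kinetics.model_copy(
                update={
                    "k_exo": kinetics.k_exo * g_mult * f_mult * b_mults[b],
                    "k_endo": kinetics.k_endo * f_mult * b_mults[b],
                }
            )
            pt = simulate_pools(kp, protocol)
            pools.append(pt)
            traces[b] = pt.f
            k_exos[b] = kp.k_exo
            k_endos[b] = kp.k_endo

        rendered = None
        if render is not None:
            rendered = render_movie(
                traces,
                render,
                rng,
                frame_interval=protocol.frame_interval,
                quantize=quantize,
            )
        nb = design.boutons_per_field
        truth = pd.DataFrame(
            {
                "prep_id": prep_id,
                "field_id": field_id,
                "group": group,
                "bouton_id": [f"{field_id}_b{b}" for b in range(nb)],
                "k_exo": k_exos,
                "k_endo": k_endos,
                "row": rendered.positions[:, 0] if rendered else np.full(nb, np.nan),
                "col": rendered.positions[:, 1] if rendered else np.full(nb, np.nan),
                "amplitude": rendered.amplitudes if rendered else np.full(nb, np.nan),
                "baseline_drift": rendered.drift_boutons if rendered else np.zeros(nb, bool),
            }
        )
        fields.append(SimulatedField(prep_id, field_id, group, rendered, truth, pools))
        truth_rows.append(truth)
        manifest_rows.append(
            {
                "file": f"{field_id}.tif",
                "prep_id": prep_id,
                "field_id": field_id,
                "group": group,
                "n_boutons": design.boutons_per_field,
                "seed": design.seed,
            }
        )

    truth_all = pd.concat(truth_rows, ignore_index=True)
    manifest = pd.DataFrame(manifest_rows)
    exp = SimulatedExperiment(fields=fields, truth=truth_all, manifest=manifest, protocol=protocol)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for fld in fields:
            if fld.rendered is not None:
                tifffile.imwrite(out / f"{fld.field_id}.tif", fld.rendered.stack.astype(np.uint16))
        manifest.to_csv(out / "manifest.csv", index=False)
        truth_all.to_csv(out / "ground_truth.csv", index=False)
    return exp
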