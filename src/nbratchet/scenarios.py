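"""Named parameterizations, figure-curve sweeps, and config-driven runs.

Presets bundle a full model parameterization -- energies, kinetics,
geometry, environment -- for the enzymes the model distinguishes:

* ``dpo4``: the archetypal L = 0 Y-family enzyme.  E_n - E_{n+1} = 3 k_B*T,
  post-translocation well depth E_r = E_{n+1} + E0 = 20.8 k_B*T (the value
  at which the processivity is ~100 nt), k_c = 9 s^-1, K_m = 230 uM.
* ``dbh``: L = 1 bp, E_n ~ E_{n+1}, E_r = 18.5 k_B*T (processivity ~10),
  k_c = 2.3e-2 s^-1, K_m = 0.4 mM.
* ``pol_iota``: structurally Dbh-like (L = 1 bp); no enzyme-specific
  kinetic constants are encoded, Dbh-like values are reused.
* ``replicative``: high single-strand affinity of the fingers site makes
  E_n - E_{n+1} = E1' - E1 = -5 k_B*T, so a backward load barely affects
  nucleotide binding.

Every preset round-trips through YAML unchanged, and each parameter value
carries a provenance note.  Figure sweeps are deterministic tables
(regenerated bit-identically) written as tidy CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .core_units import Geometry, ThermalEnvironment
from .first_passage import sawtooth_mfpt_closed_form
from .kinetics import (
    KineticParams,
    binding_rate_factor,
    cycle_monte_carlo,
    processivity,
    synthesis_rate,
)
from .landscape import RadialPotential, RatchetEnergies, Scenario, site_affinities
from .first_passage import dissociation_time

__all__ = ["ScenarioPreset", "PRESETS", "get_preset", "run_figure", "run_config", "FIGURE_TAGS"]

log = logging.getLogger("nbratchet")


class ScenarioPreset(BaseModel):
    """A named, fully-specified model parameterization."""

    model_config = ConfigDict(frozen=True)

    name: str
    scenario: Scenario
    energies: RatchetEnergies
    kinetics: KineticParams
    geometry: Geometry = Field(default_factory=Geometry)
    environment: ThermalEnvironment = Field(default_factory=ThermalEnvironment)
    notes: dict[str, str] = Field(default_factory=dict)

    @property
    def delta_e_kt(self) -> float:
        """E_n - E_{n+1} for this preset's scenario."""
        e_n, e_n1 = site_affinities(self.energies, self.scenario)
        return e_n - e_n1

    @property
    def mode(self) -> str:
        """Processivity window bookkeeping implied by the scenario."""
        return "dpo4_like" if self.scenario == "dpo4_like" else "dbh_like"

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioPreset":
        return cls.model_validate(yaml.safe_load(text))


def _dpo4() -> ScenarioPreset:
    return ScenarioPreset(
        name="dpo4",
        scenario="dpo4_like",
        energies=RatchetEnergies(
            e1_kt=0.0, e1p_kt=0.0, e2_kt=19.9, e2p_kt=16.9, e2pp_kt=11.9, e0_kt=3.9
        ),
        kinetics=KineticParams(k_c_per_s=9.0, k_m0_M=230e-6),
        geometry=Geometry(structural_offset_bp=0),
        notes={
            "e1/e1p": "fingers site has very low or no ssDNA affinity; pinned to 0",
            "e2-e2p": "3 kT: E_n - E_{n+1} = 3 kT for Dpo4 (range 3~5 kT)",
            "e2p+e0": "E_r = E_{n+1} + E0 = 20.8 kT, the N_p ~ 100 point",
            "e2p-e2pp": "5 kT one-bp backbone loss at a lesion; lesion E_r = 15.8 kT",
            "e0": "conservative electrostatic offset E0 = E_r/5 = 3.9 kT",
            "k_c, K_m": "9 s^-1 and 230 uM from steady-state kinetics",
            "t_p2": "0.065 s, from the 15.3 s^-1 activation transition rate",
        },
    )


def _dbh() -> ScenarioPreset:
    return ScenarioPreset(
        name="dbh",
        scenario="dbh_like",
        energies=RatchetEnergies(
            e1_kt=0.0, e1p_kt=0.0, e2_kt=14.8, e2p_kt=12.8, e2pp_kt=9.8, e0_kt=3.7
        ),
        kinetics=KineticParams(k_c_per_s=2.3e-2, k_m0_M=0.4e-3),
        geometry=Geometry(structural_offset_bp=1),
        notes={
            "e1/e1p": "fingers site has very low or no ssDNA affinity; pinned to 0",
            "e2": "E_n = E_{n+1} = 14.8 kT so E_r = 18.5 kT, the N_p ~ 10 point",
            "e2pp": "pinned so the lesion-site E_r = e2pp + e0 = 13.5 kT",
            "k_c, K_m": "2.3e-2 s^-1 and 0.4 mM from steady-state kinetics",
        },
    )


def _pol_iota() -> ScenarioPreset:
    base = _dbh()
    return base.model_copy(
        update={
            "name": "pol_iota",
            "notes": {
                **base.notes,
                "provenance": "structurally Dbh-like (L = 1 bp); kinetic "
                "constants are not enzyme-specific, Dbh values reused",
            },
        }
    )


def _replicative() -> ScenarioPreset:
    return ScenarioPreset(
        name="replicative",
        scenario="replicative",
        energies=RatchetEnergies(
            e1_kt=5.0, e1p_kt=0.0, e2_kt=15.0, e2p_kt=12.0, e0_kt=3.9
        ),
        kinetics=KineticParams(k_c_per_s=100.0, k_m0_M=20e-6),
        geometry=Geometry(structural_offset_bp=0),
        notes={
            "e1-e1p": "5 kT: E_n - E_{n+1} = E1' - E1 = -5 kT (range -5 ~ -3)",
            "e2": "illustrative high duplex affinity; only differences matter",
            "k_c, K_m": "illustrative replicative-polymerase scale, not a "
            "measured pair for a specific enzyme",
        },
    )


PRESETS: dict[str, ScenarioPreset] = {
    p.name: p for p in (_dpo4(), _dbh(), _pol_iota(), _replicative())
}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# figure sweeps
# ---------------------------------------------------------------------------

FIGURE_TAGS = ("fig6a", "fig6b", "fig7", "fig8", "fig9", "fig10")

_ER_GRID = np.round(np.arange(12.0, 24.0 + 1e-9, 0.1), 10)
_F_GRID = np.round(np.arange(-20.0, 30.0 + 1e-9, 0.5), 10)
_DNTP_GRID = np.logspace(-6, -2, 61)  # 1 uM .. 10 mM


def _t_d_sweep(geom: Geometry, env: ThermalEnvironment) -> pd.DataFrame:
    rows = []
    for er in _ER_GRID:
        rp = RadialPotential(
            depth_kt=float(er),
            range_nm=geom.radial_range_nm,
            escape_distance_nm=geom.escape_distance_nm,
        )
        rows.append((float(er), dissociation_time(rp, env).mean_time_s))
    return pd.DataFrame(rows, columns=["E_r_kT", "T_d_s"])


def run_figure(
    tag: str,
    overrides: Optional[Mapping] = None,
    out_dir: Optional[Path] = None,
    plot: bool = False,
) -> pd.DataFrame:
    """Regenerate one of the model's standard curves as a tidy table.

    Grids: E_r in [12, 24] k_B*T step 0.1; F in [-20, 30] pN step 0.5;
    [dNTP] on a 1 uM - 10 mM log grid.  ``overrides`` may replace the
    environment, geometry or kinetics; with ``out_dir`` the table is also
    written as ``<tag>.csv`` (plus a PNG when ``plot`` is set).
    """
    if tag not in FIGURE_TAGS:
        raise ValueError(f"unknown figure tag {tag!r}; expected one of {FIGURE_TAGS}")
    ov = dict(overrides or {})
    env: ThermalEnvironment = ov.get("environment", ThermalEnvironment())
    geom: Geometry = ov.get("geometry", Geometry())
    t_p2 = ov.get("t_p2_s", 0.065)

    if tag in ("fig6a", "fig6b"):
        df = _t_d_sweep(geom, env)
        if tag == "fig6b":
            df["N_p"] = df["T_d_s"] / t_p2
    elif tag == "fig7":
        d = env.diffusion_coefficient_m2_per_s
        l_nm = geom.half_spacing_nm
        # one table serves both directions: the forward time vs E_n at fixed
        # E_{n+1} and the backward time vs E_{n+1} at fixed E_n are the same
        # function of (escape depth, destination depth)
        e_var = np.round(np.arange(14.0, 24.0 + 1e-9, 0.1), 10)
        rows = []
        for e_fixed in (14.0, 16.0, 18.0, 20.0):
            for e in e_var:
                t = sawtooth_mfpt_closed_form(float(e), e_fixed, l_nm, d)
                rows.append((float(e), e_fixed, t))
        df = pd.DataFrame(rows, columns=["E_escape_kT", "E_destination_kT", "T_s"])
    elif tag in ("fig8", "fig9"):
        preset = get_preset("dbh" if tag == "fig8" else "dpo4")
        kp = ov.get("kinetics", preset.kinetics)
        de = preset.delta_e_kt
        rows = []
        for s in (1e-5, 1e-4, 1e-3):
            for f in _F_GRID:
                rows.append(
                    ("k_vs_F", float(f), s, synthesis_rate(kp, de, float(f), geom, env, s))
                )
        for f in (1.0, 10.0, 20.0, 30.0):
            for s in _DNTP_GRID:
                rows.append(
                    ("k_vs_S", f, float(s), synthesis_rate(kp, de, f, geom, env, float(s)))
                )
        df = pd.DataFrame(rows, columns=["panel", "F_pN", "dNTP_M", "k_per_s"])
    else:  # fig10
        rows = []
        for de in (-5.0, -4.0, -3.0, 0.0, 3.0, 5.0):
            for f in _F_GRID:
                rows.append((de, float(f), binding_rate_factor(de, float(f), geom, env)))
        df = pd.DataFrame(rows, columns=["delta_E_kT", "F_pN", "R"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / f"{tag}.csv", index=False)
        if plot:
            _plot_figure(tag, df, out_dir / f"{tag}.png")
    return df


def _plot_figure(tag: str, df: pd.DataFrame, path: Path) -> None:
    # rendering is optional and isolated: the computational core never
    # needs matplotlib
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if tag in ("fig6a", "fig6b"):
        ycol = "N_p" if tag == "fig6b" else "T_d_s"
        ax.semilogy(df["E_r_kT"], df[ycol])
        ax.set_xlabel("$E_r$ ($k_BT$)")
        ax.set_ylabel(ycol)
    elif tag == "fig7":
        for e_fixed, sub in df.groupby("E_destination_kT"):
            ax.semilogy(sub["E_escape_kT"], sub["T_s"], label=f"dest {e_fixed}")
        ax.set_xlabel("escape-well depth ($k_BT$)")
        ax.set_ylabel("moving time (s)")
        ax.legend()
    elif tag in ("fig8", "fig9"):
        sub = df[df["panel"] == "k_vs_F"]
        for s, g in sub.groupby("dNTP_M"):
            ax.plot(g["F_pN"], g["k_per_s"], label=f"[dNTP]={s:g} M")
        ax.set_xlabel("F (pN)")
        ax.set_ylabel("k (s$^{-1}$)")
        ax.legend()
    else:
        for de, g in df.groupby("delta_E_kT"):
            ax.plot(g["F_pN"], g["R"], label=f"$\\Delta E$={de:g}")
        ax.set_xlabel("F (pN)")
        ax.set_ylabel("$k_b(F)/k_b(0)$")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# config-driven runs
# ---------------------------------------------------------------------------


class RunSection(BaseModel):
    analyses: list[str] = Field(default_factory=lambda: ["processivity"])
    figures: list[str] = Field(default_factory=list)
    seed: int = 0
    force_pN: float = 0.0
    n_traj: int = 200

    def model_post_init(self, __context) -> None:
        known = {"processivity", "moving_times", "force_response", "figures", "cycle_sim"}
        bad = set(self.analyses) - known
        if bad:
            raise ValueError(f"unknown analyses {sorted(bad)}; known: {sorted(known)}")
        bad_figs = set(self.figures) - set(FIGURE_TAGS)
        if bad_figs:
            raise ValueError(f"unknown figure tags {sorted(bad_figs)}")


class RunConfigModel(BaseModel):
    preset: Optional[str] = None
    scenario: Optional[Scenario] = None
    environment: dict = Field(default_factory=dict)
    geometry: dict = Field(default_factory=dict)
    energies: Optional[dict] = None
    kinetics: dict = Field(default_factory=dict)
    run: RunSection = Field(default_factory=RunSection)

    def resolve(self) -> ScenarioPreset:
        """Merge preset defaults with overrides into a concrete preset."""
        if self.preset is not None:
            base = get_preset(self.preset)
        else:
            if self.energies is None or self.scenario is None:
                raise ValueError("config without 'preset' needs 'scenario' and 'energies'")
            base = ScenarioPreset(
                name="custom",
                scenario=self.scenario,
                energies=RatchetEnergies(**self.energies),
                kinetics=KineticParams(**self.kinetics) if self.kinetics else KineticParams(
                    k_c_per_s=1.0, k_m0_M=1e-4
                ),
            )
        upd: dict = {}
        if self.environment:
            upd["environment"] = base.environment.model_copy(update=self.environment)
        if self.geometry:
            upd["geometry"] = base.geometry.model_copy(update=self.geometry)
        if self.preset is not None and self.energies:
            upd["energies"] = base.energies.model_copy(update=self.energies)
        if self.preset is not None and self.kinetics:
            upd["kinetics"] = base.kinetics.model_copy(update=self.kinetics)
        if self.scenario is not None and self.preset is not None:
            upd["scenario"] = self.scenario
        return base.model_copy(update=upd)


def run_config(path, out_dir=None) -> dict:
    """Execute the analyses requested by a YAML config file.

    Writes one CSV per analysis plus ``manifest.json`` (all resolved
    parameters, seed, package version, produced files) to ``out_dir``
    (default: alongside the config).  A failing analysis is recorded and
    re-raised after the remaining ones have run, so completed outputs are
    retained.
    """
    path = Path(path)
    cfg = RunConfigModel.model_validate(yaml.safe_load(path.read_text()) or {})
    preset = cfg.resolve()
    out = Path(out_dir) if out_dir is not None else path.parent / f"{path.stem}_out"
    out.mkdir(parents=True, exist_ok=True)
    env, geom, kp = preset.environment, preset.geometry, preset.kinetics
    produced: list[str] = []
    errors: list[str] = []

    def _write(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False)
        produced.append(name)
        log.info("wrote %s", p)

    for analysis in cfg.run.analyses:
        try:
            if analysis == "processivity":
                res = processivity(preset.energies, kp, geom, env, preset.mode)
                _write(
                    "processivity.csv",
                    pd.DataFrame(
                        [
                            {
                                "preset": preset.name,
                                "N_p": res.n_p,
                                "P_d1": res.p_d1,
                                "P_d2": res.p_d2,
                                "T_d_site_n1_s": res.t_d_s["site_n1"],
                            }
                        ]
                    ),
                )
            elif analysis == "moving_times":
                from .first_passage import moving_time

                e_n, e_n1 = site_affinities(preset.energies, preset.scenario)
                fwd = moving_time(e_n, e_n1, geom, env).mean_time_s
                bwd = moving_time(e_n1, e_n, geom, env).mean_time_s
                _write(
                    "moving_times.csv",
                    pd.DataFrame(
                        [{"preset": preset.name, "T_fwd_s": fwd, "T_bwd_s": bwd}]
                    ),
                )
            elif analysis == "force_response":
                de = preset.delta_e_kt
                rows = [
                    {
                        "F_pN": float(f),
                        "R": binding_rate_factor(de, float(f), geom, env),
                        "k_per_s": synthesis_rate(kp, de, float(f), geom, env),
                    }
                    for f in _F_GRID
                ]
                _write("force_response.csv", pd.DataFrame(rows))
            elif analysis == "cycle_sim":
                res = cycle_monte_carlo(
                    preset.energies, kp, geom, env, preset.mode,
                    seed=cfg.run.seed, n_traj=cfg.run.n_traj,
                )
                _write(
                    "cycle_sim.csv",
                    pd.DataFrame(
                        [
                            {
                                "preset": preset.name,
                                "seed": cfg.run.seed,
                                "n_traj": cfg.run.n_traj,
                                "N_p": res.n_p,
                                "N_p_sem": res.n_p_sem,
                                "velocity_nt_per_s": res.velocity_nt_per_s,
                            }
                        ]
                    ),
                )
            elif analysis == "figures":
                for tag in cfg.run.figures:
                    run_figure(
                        tag,
                        overrides={"environment": env, "geometry": geom, "kinetics": kp},
                        out_dir=out,
                    )
                    produced.append(f"{tag}.csv")
        except Exception as exc:  # keep completed outputs, report at the end
            log.error("analysis %r failed: %s", analysis, exc)
            errors.append(f"{analysis}: {exc}")

    manifest = {
        "config": str(path),
        "package_version": __version__,
        "seed": cfg.run.seed,
        "parameters": preset.model_dump(),
        "outputs": produced,
        "errors": errors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if errors:
        raise RuntimeError("; ".join(errors))
    return manifest
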