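"""Plain-text readers/writers, run configuration and the staged pipeline.

File formats are deliberately simple 2-column text with ``# key = value``
header lines, so that every artifact survives version control and diffing.
Instrument-native binary formats are out of scope; import adapters can be
layered on top of :func:`read_decay_file` / :func:`read_cd_file`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import report as report_mod
from . import synthetic, tcspc
from .cd import (
    CDSpectrum,
    average_scans,
    baseline_subtract,
    exciton_metrics,
    percent_signal_change,
    smooth_means_movement,
    to_delta_epsilon,
)
from .exceptions import ConfigurationError, DataFormatError
from .tcspc import DecayCurve

__all__ = [
    "RunConfig",
    "read_decay_file",
    "write_decay_file",
    "read_cd_file",
    "write_cd_file",
    "run_pipeline",
]

log = logging.getLogger("excispec")

_FLOAT = np.float64


def _fmt(x: float) -> str:
    """Shortest representation that round-trips a float64 exactly."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# decay files
# ---------------------------------------------------------------------------

def write_decay_file(path, curve: DecayCurve) -> None:
    lines = ["# kind = decay"]
    if curve.wavelength is not None:
        lines.append(f"# wavelength_nm = {_fmt(curve.wavelength)}")
    for k, v in curve.metadata.items():
        if k == "kind":
            continue
        lines.append(f"# {k} = {v}")
    lines.append("# columns = time_ns counts")
    for t, c in zip(curve.times, curve.counts):
        lines.append(f"{_fmt(t)}\t{_fmt(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_header(raw_lines):
    meta, data_lines = {}, []
    for lineno, line in enumerate(raw_lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        data_lines.append((lineno, s))
    return meta, data_lines


def _parse_columns(data_lines, path):
    col1, col2 = [], []
    for lineno, s in data_lines:
        parts = s.split()
        if len(parts) != 2:
            raise DataFormatError(f"{path}: line {lineno}: expected 2 columns")
        try:
            a, b = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise DataFormatError(f"{path}: line {lineno}: {exc}") from None
        col1.append((lineno, a))
        col2.append((lineno, b))
    return col1, col2


def read_decay_file(path) -> DecayCurve:
    """Read a 2-column (time_ns, counts) text file with ``#`` headers."""
    raw = Path(path).read_text().splitlines()
    meta, data_lines = _parse_header(raw)
    if not data_lines:
        raise DataFormatError(f"{path}: no data rows")
    times_l, counts_l = _parse_columns(data_lines, path)
    for lineno, c in counts_l:
        if c < 0:
            raise DataFormatError(f"{path}: line {lineno}: negative count {c}")
    times = np.array([t for _, t in times_l], dtype=_FLOAT)
    counts = np.array([c for _, c in counts_l], dtype=_FLOAT)
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
        raise DataFormatError(f"{path}: time grid not uniform/increasing")
    wavelength = None
    if "wavelength_nm" in meta:
        wavelength = float(meta.pop("wavelength_nm"))
    meta.pop("columns", None)
    meta.pop("kind", None)
    return DecayCurve(times, counts, wavelength=wavelength, metadata=meta)


# ---------------------------------------------------------------------------
# CD files
# ---------------------------------------------------------------------------

def write_cd_file(path, spectrum: CDSpectrum) -> None:
    lines = [f"# units = {spectrum.units}", f"# n_scans = {spectrum.n_scans}"]
    for k, v in spectrum.metadata.items():
        lines.append(f"# {k} = {v}")
    lines.append("# columns = wavelength_nm value")
    for w, v in zip(spectrum.wavelengths, spectrum.values):
        lines.append(f"{_fmt(w)}\t{_fmt(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cd_file(path, allow_any_spacing: bool = False) -> CDSpectrum:
    """Read a 2-column (wavelength_nm, value) file; units header required."""
    raw = Path(path).read_text().splitlines()
    meta, data_lines = _parse_header(raw)
    if "units" not in meta:
        raise DataFormatError(f"{path}: missing '# units = ...' header")
    units = meta.pop("units")
    n_scans = int(meta.pop("n_scans", 1))
    meta.pop("columns", None)
    if not data_lines:
        raise DataFormatError(f"{path}: no data rows")
    wl_l, val_l = _parse_columns(data_lines, path)
    wl = np.array([w for _, w in wl_l], dtype=_FLOAT)
    vals = np.array([v for _, v in val_l], dtype=_FLOAT)
    if wl.size >= 2 and not allow_any_spacing:
        step = wl[1] - wl[0]
        if abs(step - 0.5) > 1e-9:
            raise DataFormatError(
                f"{path}: grid spacing {step} nm != 0.5 nm "
                "(pass allow_any_spacing=True to override)"
            )
    try:
        return CDSpectrum(wl, vals, units=units, n_scans=n_scans, metadata=meta)
    except ConfigurationError as exc:
        raise DataFormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative configuration for the staged pipeline."""

    channels: int = 4096
    window_ns: float = 50.0
    irf_fwhm_ps: float = 80.0
    irf_t0_ns: float = 2.0
    irf_file: str | None = None
    wavelengths: list = field(default_factory=lambda: [370.0, 380.0, 390.0])
    peak_counts: int = 10_000
    background: float = 0.0
    sample_preset: str = "y40a_substrate"
    ds_reference_preset: str = "double_flap"
    ss_reference_preset: str = "single_strand"
    n_components: int | None = 4           # None -> model-order search
    max_components: int = 6
    alpha: float = 0.05
    n_boot: int = 0                        # bootstrap replicates (0 = skip)
    fit_shift: bool = True
    dna_concentration_m: float = 1e-5      # 10 uM construct
    residues_2ap_per_strand: int = 2
    pathlength_cm: float = 1.0
    smoothing_width: int = 5
    cd_n_scans: int = 5
    cd_unpaired_fractions: list = field(
        default_factory=lambda: [0.0, 0.25, 0.51, 0.83, 0.98]
    )
    cd_noise_sd: float = 0.02
    seed: int = 1
    outdir: str = "out"
    make_plots: bool = False

    def __post_init__(self) -> None:
        positive = {
            "channels": self.channels, "window_ns": self.window_ns,
            "irf_fwhm_ps": self.irf_fwhm_ps, "peak_counts": self.peak_counts,
            "dna_concentration_m": self.dna_concentration_m,
            "residues_2ap_per_strand": self.residues_2ap_per_strand,
            "pathlength_cm": self.pathlength_cm,
            "smoothing_width": self.smoothing_width,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive (got {v})")
        if not self.wavelengths:
            raise ConfigurationError("wavelengths must not be empty")
        if self.seed is None:
            raise ConfigurationError("a master seed is required")
        for name in (self.sample_preset, self.ds_reference_preset,
                     self.ss_reference_preset):
            if name not in synthetic.PRESETS:
                raise ConfigurationError(
                    f"unknown preset {name!r}; available: "
                    f"{sorted(synthetic.PRESETS)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def conc_2ap(self) -> float:
        return self.dna_concentration_m * self.residues_2ap_per_strand


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _irf_for(config: RunConfig) -> DecayCurve:
    if config.irf_file:
        return read_decay_file(config.irf_file)
    grid = synthetic.make_time_grid(config.channels, config.window_ns)
    spec = synthetic.IRFSpec(fwhm=config.irf_fwhm_ps / 1000.0,
                             t0=config.irf_t0_ns)
    return synthetic.make_irf(spec, grid)


def _condition_names(config: RunConfig) -> dict:
    return {
        "sample": config.sample_preset,
        "ds_ref": config.ds_reference_preset,
        "ss_ref": config.ss_reference_preset,
    }


class Pipeline:
    """Stage runner sharing state between simulate/fit/cd/report."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.irf = None
        self.curves: dict = {}       # condition -> list[DecayCurve]
        self.fits: dict = {}         # condition -> GlobalFitResult
        self.artifacts: list = []

    # -- helpers ---------------------------------------------------------
    def _write(self, relpath: str, writer, *args) -> Path:
        path = self.outdir / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path, *args)
        self.artifacts.append(relpath)
        return path

    def _write_text(self, relpath: str, text: str) -> Path:
        return self._write(relpath, lambda p, t: Path(p).write_text(t), text)

    # -- stages ----------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.config
        log.info("stage=simulate seed=%s outdir=%s", cfg.seed, cfg.outdir)
        self.irf = _irf_for(cfg)
        self._write("irf.txt", write_decay_file, self.irf)
        for i, (cond, preset) in enumerate(_condition_names(cfg).items()):
            comps, _ = synthetic.PRESETS[preset]
            curves = synthetic.simulate_global_set(
                comps, self.irf, cfg.wavelengths, cfg.peak_counts,
                cfg.background, seed=cfg.seed + i,
            )
            self.curves[cond] = curves
            for c in curves:
                c.metadata["preset"] = preset
                self._write(f"decays/{cond}_{c.wavelength:g}nm.txt",
                            write_decay_file, c)
        grid = synthetic.default_cd_grid()
        for k, f in enumerate(cfg.cd_unpaired_fractions):
            for scan in range(cfg.cd_n_scans):
                sub = cfg.seed * 1000 + k * 10 + scan
                spec = synthetic.CDCoupletSpec(unpaired_fraction=f,
                                               noise_sd=cfg.cd_noise_sd)
                s = synthetic.simulate_cd_spectrum(
                    spec, grid, seed=sub, units="mdeg",
                    conc_2ap=cfg.conc_2ap, pathlength=cfg.pathlength_cm,
                )
                self._write(f"cd/f{f:g}_scan{scan}.txt", write_cd_file, s)
                blank_spec = synthetic.CDCoupletSpec(
                    unpaired_fraction=1.0, noise_sd=cfg.cd_noise_sd)
                blank = synthetic.simulate_cd_spectrum(
                    blank_spec, grid, seed=sub + 500_000, units="mdeg",
                    conc_2ap=cfg.conc_2ap, pathlength=cfg.pathlength_cm,
                )
                self._write(f"cd/f{f:g}_blank{scan}.txt", write_cd_file, blank)

    def _load_inputs(self) -> None:
        if self.irf is None:
            irf_path = self.outdir / "irf.txt"
            if self.config.irf_file is None and not irf_path.exists():
                raise ConfigurationError(
                    "fit stage needs simulated inputs or an irf_file; "
                    "run the simulate stage first"
                )
            self.irf = read_decay_file(irf_path) if irf_path.exists() \
                else _irf_for(self.config)
        if not self.curves:
            decay_dir = self.outdir / "decays"
            if not decay_dir.is_dir():
                raise ConfigurationError(
                    f"no decay files under {decay_dir}; run simulate first"
                )
            for cond in _condition_names(self.config):
                files = sorted(decay_dir.glob(f"{cond}_*nm.txt"))
                if not files:
                    raise ConfigurationError(f"no decay files for {cond!r}")
                self.curves[cond] = [read_decay_file(f) for f in files]

    def fit(self) -> None:
        cfg = self.config
        self._load_inputs()
        for cond, curves in self.curves.items():
            if cfg.n_components is None:
                n = tcspc.select_model_order(
                    curves, self.irf, cfg.max_components, cfg.alpha,
                    fit_shift=cfg.fit_shift,
                )
            else:
                n = cfg.n_components
            log.info("stage=fit condition=%s n_components=%d", cond, n)
            res = tcspc.fit_global(curves, self.irf, n,
                                   fit_shift=cfg.fit_shift)
            if cfg.n_boot > 0:
                tcspc.estimate_uncertainties(res, curves, self.irf,
                                             n_boot=cfg.n_boot,
                                             seed=cfg.seed,
                                             fit_shift=cfg.fit_shift)
            self.fits[cond] = res
            self._write_text(f"fits/{cond}_params.tsv", _fit_table(res))
            self._write_text(f"fits/{cond}_summary.txt", _fit_summary(cond, res))

    def cd(self) -> None:
        cfg = self.config
        cd_dir = self.outdir / "cd"
        if not cd_dir.is_dir():
            raise ConfigurationError(f"no CD files under {cd_dir}; "
                                     "run simulate first")
        processed = {}
        for f in cfg.cd_unpaired_fractions:
            scans = [read_cd_file(p) for p in
                     sorted(cd_dir.glob(f"f{f:g}_scan*.txt"))]
            blanks = [read_cd_file(p) for p in
                      sorted(cd_dir.glob(f"f{f:g}_blank*.txt"))]
            if not scans or not blanks:
                raise ConfigurationError(f"missing CD scans for fraction {f}")
            spec = baseline_subtract(average_scans(scans), average_scans(blanks))
            spec = smooth_means_movement(spec, cfg.smoothing_width)
            spec = to_delta_epsilon(spec, cfg.conc_2ap, cfg.pathlength_cm)
            processed[f] = exciton_metrics(spec)
            self._write(f"cd/f{f:g}_processed.txt", write_cd_file, spec)
        ref = processed[cfg.cd_unpaired_fractions[0]]
        rows = ["fraction\tamplitude_330\tband_mean_320_330\tpeak_nm\tpct_change"]
        for f, m in processed.items():
            pct = percent_signal_change(m, ref)
            rows.append(f"{f:g}\t{_fmt(m.amplitude_330)}\t"
                        f"{_fmt(m.band_mean_320_330)}\t"
                        f"{m.peak_wavelength:g}\t{_fmt(pct)}")
        self._write_text("cd/metrics.tsv", "\n".join(rows) + "\n")

    def report(self) -> None:
        if not self.fits:
            self.fit()
        sample = self.fits["sample"]
        ds = self.fits["ds_ref"]
        ss = self.fits["ss_ref"]
        state = report_mod.classify_components(sample)
        changes = report_mod.percent_param_change(sample, ds)
        mix = report_mod.estimate_mixture_fraction(
            self.curves["sample"], ds, ss, self.irf)
        state.percent_changes = changes
        state.mixture_fraction = mix.fraction

        rows = ["quantity\tvalue"]
        for cls in report_mod.CLASS_NAMES:
            rows.append(f"population_{cls}\t{_fmt(state.populations[cls])}")
        for i, (dt, da) in enumerate(zip(changes["tau"], changes["A"]), start=1):
            rows.append(f"pct_change_tau{i}\t{_fmt(dt)}")
            rows.append(f"pct_change_A{i}\t{_fmt(da)}")
        rows.append(f"mixture_fraction_unpaired\t{_fmt(mix.fraction)}")
        rows.append(f"mixture_residual\t{_fmt(mix.residual)}")
        self._write_text("report/state_report.tsv", "\n".join(rows) + "\n")
        self._write_text("report/report.txt", _human_report(state, mix))
        if self.config.make_plots:
            from . import plots
            fig_dir = self.outdir / "report"
            plots.afactor_vs_lifetime(
                {"sample": sample, "ds_ref": ds, "ss_ref": ss},
                fig_dir / "afactor_vs_tau.png")
            plots.percent_change_bars(changes, fig_dir / "percent_change.png")

    def manifest(self, status: str) -> None:
        payload = {"status": status, "seed": self.config.seed,
                   "artifacts": sorted(self.artifacts)}
        self._write_text("manifest.json", json.dumps(payload, indent=2) + "\n")


def _fit_table(res: tcspc.GlobalFitResult) -> str:
    unc = res.uncertainties
    rows = ["component\ttau_ns\ttau_rel_unc\tA_sample\tA_sample_rel_unc"
            + "".join(f"\tA_{w:g}nm" for w in res.wavelengths)]
    a_sample = res.sample_a_factors
    for i in range(res.model.n_components):
        tau_u = _fmt(unc["lifetimes_rel"][i]) if unc else "NA"
        a_u = _fmt(unc["sample_a_factors_rel"][i]) if unc else "NA"
        per_wl = "".join(f"\t{_fmt(res.a_factors[j, i])}"
                         for j in range(len(res.wavelengths)))
        rows.append(f"{i + 1}\t{_fmt(res.lifetimes[i])}\t{tau_u}\t"
                    f"{_fmt(a_sample[i])}\t{a_u}{per_wl}")
    return "\n".join(rows) + "\n"


def _fit_summary(cond: str, res: tcspc.GlobalFitResult) -> str:
    lines = [
        f"condition: {cond}",
        f"converged: {res.converged}",
        f"n_components: {res.model.n_components}",
        f"fit_range_channels: {res.fit_range[0]}..{res.fit_range[1]}",
        f"chisq_reduced_global: {_fmt(res.chisq_reduced_global)}",
    ]
    for j, wl in enumerate(res.wavelengths):
        lines.append(
            f"curve {wl} nm: chisq_r={_fmt(res.chisq_reduced[j])} "
            f"runs_p={_fmt(res.residual_randomness[j])} "
            f"shift={_fmt(res.model.shifts[j])} "
            f"background={_fmt(res.model.backgrounds[j])}"
        )
    return "\n".join(lines) + "\n"


def _human_report(state, mix) -> str:
    lines = ["Conformational population report", ""]
    lines.append("Stacking-class populations (fractions of emitting population):")
    for cls in report_mod.CLASS_NAMES:
        lines.append(f"  {cls:24s} {state.populations[cls]:.4f}")
    lines.append("")
    lines.append("Percentage change vs duplex reference (components 1-3):")
    for i, (dt, da) in enumerate(
            zip(state.percent_changes["tau"], state.percent_changes["A"]),
            start=1):
        lines.append(f"  tau{i}: {dt:+.1f}%   A{i}: {da:+.1f}%")
    lines.append("")
    lines.append(f"Two-state unpaired fraction: {mix.fraction:.3f} "
                 f"(residual {mix.residual:.4f})")
    lines.append("Note: populations describe the 2AP stacking environment, "
                 "not base pairing directly.")
    return "\n".join(lines) + "\n"


STAGES = ("simulate", "fit", "cd", "report")


def run_pipeline(config: RunConfig, mode: str = "all") -> Pipeline:
    """Execute the requested stage(s); 'all' runs simulate-fit-cd-report."""
    if mode not in STAGES + ("all",):
        raise ConfigurationError(f"unknown mode {mode!r}")
    pipe = Pipeline(config)
    stages = STAGES if mode == "all" else (mode,)
    try:
        for stage in stages:
            getattr(pipe, stage)()
    except Exception:
        pipe.manifest("failed")
        raise
    pipe.manifest("ok")
    return pipe
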