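"""End-to-end multi-clade pipeline: per-clade DEC reconstruction, pooled
event classification, MDE curves with bootstrap features, change points and
habitat reports, written to an output directory with provenance headers.

A clade directory holds, per clade ``<name>``:

* ``<name>.nwk`` or ``<name>.nex`` — dated tree;
* ``<name>.ranges.tsv`` — focal/non-focal range coding (two columns);
* ``<name>.regions.tsv`` — optional finer regional coding (source areas);
* ``<name>.habitat.tsv`` — optional open/closed/both habitat coding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .changepoint import select_changepoints
from .dec import AreaScheme, DECModel
from .events import assign_sources, classify_events, tally
from .habitat import MkModel, preadaptation_report, read_habitat_coding
from .mde import bootstrap_features, mde_curve, peak, per_source_curves, support_onset
from .treeio import EventTable, read_coding, read_tree, write_event_table

logger = logging.getLogger(__name__)

EVENT_LABELS = {"dispersal_in": "MDisE", "in_situ": "MDivE"}


@dataclass
class MDEOptions:
    bin_width: float = 0.1
    window: float = 0.5
    n_boot: int = 1000
    seed: int = 0
    mode: str = "interval-age"
    per_ma: bool = False


@dataclass
class ChangepointOptions:
    k_candidates: tuple[int, ...] = (1, 2, 3, 4)
    n_random_starts: int = 5


@dataclass
class HabitatOptions:
    model: str = "equal-rates"
    threshold: float = 0.8


@dataclass
class RunConfig:
    """Resolved pipeline configuration; defaults follow the standard analysis settings
    (0.1-Ma slices, 0.5-Ma window, 1000 bootstrap replicates, k in 1..4)."""

    clades_dir: str
    output_dir: str
    scheme: AreaScheme
    regions_scheme: AreaScheme | None = None
    mde: MDEOptions = field(default_factory=MDEOptions)
    changepoint: ChangepointOptions = field(default_factory=ChangepointOptions)
    habitat: HabitatOptions = field(default_factory=HabitatOptions)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def scheme_of(d):
            if d is None:
                return None
            mult = d.get("multipliers")
            return AreaScheme(
                areas=tuple(d["areas"]), focal_area=d["focal_area"],
                max_range_size=d.get("max_range_size"),
                slice_boundaries=tuple(d.get("slice_boundaries") or ()),
                multipliers=[np.asarray(m, dtype=float) for m in mult]
                if mult else None)

        return cls(
            clades_dir=raw["clades_dir"],
            output_dir=raw["output_dir"],
            scheme=scheme_of(raw["scheme"]),
            regions_scheme=scheme_of(raw.get("regions_scheme")),
            mde=MDEOptions(**raw.get("mde", {})),
            changepoint=ChangepointOptions(**{
                k: tuple(v) if k == "k_candidates" else v
                for k, v in raw.get("changepoint", {}).items()}),
            habitat=HabitatOptions(**raw.get("habitat", {})),
            log_level=raw.get("log_level", "INFO"),
        )

    def to_dict(self) -> dict:
        def scheme_dict(s):
            if s is None:
                return None
            return {"areas": list(s.areas), "focal_area": s.focal_area,
                    "max_range_size": s.max_range_size,
                    "slice_boundaries": list(s.slice_boundaries),
                    "multipliers": [m.tolist() for m in s.multipliers]
                    if s.multipliers is not None else None}

        return {"clades_dir": self.clades_dir, "output_dir": self.output_dir,
                "scheme": scheme_dict(self.scheme),
                "regions_scheme": scheme_dict(self.regions_scheme),
                "mde": asdict(self.mde),
                "changepoint": {"k_candidates": list(self.changepoint.k_candidates),
                                "n_random_starts": self.changepoint.n_random_starts},
                "habitat": asdict(self.habitat),
                "log_level": self.log_level}

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (where outputs land and
        how verbosely we log do not change the numbers)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def discover_clades(clades_dir: str) -> list[dict]:
    """Find per-clade input files (tree + range coding, optional extras)."""
    root = Path(clades_dir)
    clades = []
    for tree_path in sorted(list(root.glob("*.nwk")) + list(root.glob("*.nex"))):
        stem = tree_path.stem
        ranges = root / f"{stem}.ranges.tsv"
        if not ranges.exists():
            logger.warning("skipping %s: no %s", tree_path.name, ranges.name)
            continue
        clades.append({
            "name": stem,
            "tree": str(tree_path),
            "format": "nexus" if tree_path.suffix == ".nex" else "newick",
            "ranges": str(ranges),
            "regions": str(root / f"{stem}.regions.tsv")
            if (root / f"{stem}.regions.tsv").exists() else None,
            "habitat": str(root / f"{stem}.habitat.tsv")
            if (root / f"{stem}.habitat.tsv").exists() else None,
        })
    return clades


def provenance(config: RunConfig, extra: dict | None = None) -> dict[str, str]:
    out = {"tool": f"biogeodyn {__version__}",
           "config_hash": config.config_hash(),
           "seed": str(config.mde.seed)}
    out.update(extra or {})
    return out


def _write_table(df, path: Path, prov: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Stages: per-clade DEC fit and ancestral ranges -> pooled event table ->
    MDisE/MDivE curves, bootstrap features and change points -> per-source
    curves -> habitat reports -> summary. A stage failure aborts with the
    stage and clade named; outputs written so far are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    clades = discover_clades(config.clades_dir)
    if not clades:
        raise FileNotFoundError(f"no clade inputs found in {config.clades_dir}")
    prov = provenance(config)

    all_events: list = []
    habitat_blocks: list[str] = []
    for clade in clades:
        name = clade["name"]
        stage = "read"
        try:
            tree = read_tree(clade["tree"], format=clade["format"], clade_id=name)
            coding = read_coding(clade["ranges"], alphabet=config.scheme.areas)
            stage = "dec-fit"
            model = DECModel(tree, coding, config.scheme)
            res = model.fit()
            stage = "ancestral"
            anc = res.ancestral_ranges()
            _write_table(anc.to_frame(), out / f"{name}.ancestral.tsv",
                         {**prov, "clade": name,
                          "d": f"{res.params.d:.6g}", "e": f"{res.params.e:.6g}"})
            stage = "classify"
            ev = classify_events(tree, anc, coding, config.scheme)
            if clade["regions"] and config.regions_scheme is not None and len(ev):
                stage = "sources"
                reg_coding = read_coding(clade["regions"],
                                         alphabet=config.regions_scheme.areas)
                reg_res = DECModel(tree, reg_coding, config.regions_scheme).fit()
                ev = assign_sources(ev, tree, reg_res.ancestral_ranges(),
                                    reg_coding, config.regions_scheme)
            all_events.extend(ev)
            if clade["habitat"]:
                stage = "habitat"
                hab = read_habitat_coding(clade["habitat"])
                hres = MkModel(tree, hab, model=config.habitat.model).fit()
                table = hres.ancestral_states()
                _write_table(table, out / f"{name}.habitat.tsv",
                             {**prov, "clade": name, "mk_model": config.habitat.model})
                rep = preadaptation_report(tree, table, EventTable(list(ev)),
                                           threshold=config.habitat.threshold)
                if rep.n_events:
                    habitat_blocks.append(f"{name}: {rep.summary()}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed for clade {name!r}: {exc}") from exc

    events = EventTable(all_events, provenance=prov)
    write_event_table(events, str(out / "events.tsv"))

    lines = [tally(events).summary(), ""]
    feature_lines = []
    for etype, label in EVENT_LABELS.items():
        sub = events.of_type(etype)
        if not len(sub):
            lines.append(f"{label}: no events")
            continue
        curve = mde_curve(sub, bin_width=config.mde.bin_width,
                          window=config.mde.window, per_ma=config.mde.per_ma)
        _write_table(curve.to_frame(), out / f"{label.lower()}_curve.tsv",
                     {**prov, "event_type": etype})
        feat = bootstrap_features(sub, n_boot=config.mde.n_boot,
                                  seed=config.mde.seed, mode=config.mde.mode,
                                  bin_width=config.mde.bin_width,
                                  window=config.mde.window)
        feature_lines.append(f"Origination of {label}: "
                             f"{feat.origination:.2f} "
                             f"({feat.origination_ci[0]:.2f}-{feat.origination_ci[1]:.2f})")
        pk = feat.peak
        if pk.defined:
            feature_lines.append(f"Peak of {label}: {pk.age:.2f} "
                                 f"({feat.peak_ci[0]:.2f}-{feat.peak_ci[1]:.2f})")
        x = curve.midpoints
        if len(x) >= 2 * max(config.changepoint.k_candidates) + 4:
            best, table = select_changepoints(
                x, curve.smoothed, k_candidates=config.changepoint.k_candidates,
                n_random_starts=config.changepoint.n_random_starts,
                seed=config.mde.seed)
            _write_table(table, out / f"{label.lower()}_bic.tsv", prov)
            with open(out / f"{label.lower()}_changepoints.txt", "w") as fh:
                fh.write(best.summary() + "\n")
            cps = ", ".join(f"{p:.2f} ({o:.2f}-{y:.2f})" if np.isfinite(o)
                            else f"{p:.2f}"
                            for p, (o, y) in best.breakpoints_by_age())
            feature_lines.append(f"Change points of {label}: {cps}")
        lines.append(f"{label}: {len(sub)} events; support onset "
                     f"{support_onset(curve):.2f} Ma; "
                     f"peak {peak(curve).age:.2f} Ma")

    for region, curve in per_source_curves(
            events, bin_width=config.mde.bin_width,
            window=config.mde.window).items():
        _write_table(curve.to_frame(), out / f"mdise_source_{region}.tsv",
                     {**prov, "source_region": region})

    if feature_lines:
        lines += ["", "Features of the assembly dynamics (Ma, 95% CI):"]
        lines += feature_lines
    if habitat_blocks:
        lines += ["", "Ancestral habitat of dispersing lineages:"] + habitat_blocks
    summary = "\n".join(lines) + "\n"
    with open(out / "summary.txt", "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}: {v}\n")
        fh.write(summary)
    logger.info("pipeline complete: %s", out)
    return out
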