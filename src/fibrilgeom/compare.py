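"""Side-by-side structural comparison of two fibril models.

Runs every analysis stage on both models with one shared configuration
and collects the results into a single report: twist handedness by both
routes (delta statistic and helical superposition), helical geometry,
strand counts, core residue ranges, axial register, stack stagger, layer
charges and charge asymmetry, plus a difference block flagging sign flips
between the two models.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .charge import ChargeConfig, charge_asymmetry, layer_net_charge
from .geometry import (backbone_dihedrals, delta_statistic, helical_parameters,
                       model_width)
from .model import FibrilModel
from .register import axial_shift, stack_stagger
from .strands import classify_beta, segment_strands, BetaWindow

log = logging.getLogger(__name__)


@dataclass
class CompareConfig:
    """Shared analysis parameters for a two-model comparison."""

    pH: float = 7.4
    charge_mode: str = "integer"
    include_termini: bool = True
    beta_phi_range: tuple = (-180.0, -30.0)
    beta_psi_ranges: tuple = ((60.0, 180.0), (-180.0, -150.0))
    min_strand_length: int = 2
    max_strand_gap: int = 1
    register_pair: tuple = (2, 29)

    def beta_window(self) -> BetaWindow:
        return BetaWindow(phi_range=tuple(self.beta_phi_range),
                          psi_ranges=tuple(tuple(r) for r in self.beta_psi_ranges))

    def charge_config(self) -> ChargeConfig:
        return ChargeConfig(pH=self.pH, mode=self.charge_mode,
                            include_termini=self.include_termini)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ComparisonReport:
    models: dict = field(default_factory=dict)     # name -> analysis block
    differences: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, indent: int = 1) -> str:
        return json.dumps({"models": self.models,
                           "differences": self.differences,
                           "provenance": self.provenance,
                           "warnings": self.warnings},
                          indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        d = json.loads(text)
        return cls(models=d["models"], differences=d["differences"],
                   provenance=d["provenance"], warnings=d.get("warnings", []))


def core_residue_range(model: FibrilModel, stack: str) -> tuple[int, int]:
    """First and last author residue number with a resolved C-alpha in the
    chains of one stack."""
    chains = model.chains_in_stack(stack)
    if not chains:
        raise ValueError(f"no stack {stack!r} in model")
    nums = []
    for c in chains:
        resnums, _ = model.ca_coords(c)
        nums.extend(resnums.tolist())
    return int(min(nums)), int(max(nums))


def analyze_model(model: FibrilModel, config: CompareConfig | None = None,
                  name: str = "model") -> dict:
    """Full single-model analysis block of the comparison report."""
    config = config or CompareConfig()
    window = config.beta_window()
    ccfg = config.charge_config()
    warnings: list[str] = []
    block: dict = {"name": name}
    central = model.central_layer()

    block["stacks"] = {}
    for stack in (model.stacks or ["A"]):
        sblock: dict = {}
        # delta statistic pooled over all chains of the stack
        records = []
        for chain in model.chains_in_stack(stack):
            records.extend(classify_beta(backbone_dihedrals(model, chain), window))
        try:
            summary = delta_statistic(records, subset="beta")
            sblock["delta_mean_deg"] = summary.delta_mean_deg
            sblock["delta_sd_deg"] = summary.delta_sd_deg
            sblock["n_beta_residues"] = summary.n_residues
            sblock["right_side_fraction"] = summary.right_side_fraction
            sblock["handedness_call"] = summary.handedness_call
        except ValueError:
            warnings.append(f"{name}/{stack}: no beta residues for delta statistic")
        # strand count on the central-layer chain of the stack
        chain = model.chain_for(central, stack)
        if chain is not None:
            recs = classify_beta(backbone_dihedrals(model, chain), window)
            segs = segment_strands(recs, config.min_strand_length,
                                   config.max_strand_gap)
            sblock["n_strands"] = len(segs)
            sblock["strands"] = [(s.start_residue, s.end_residue) for s in segs]
        sblock["core_range"] = list(core_residue_range(model, stack))
        # axial register in the central-layer chain
        a, b = config.register_pair
        if chain is not None:
            try:
                sh = axial_shift(model, chain, a, b)
                sblock["axial_shift_A"] = sh.shift_A
                sblock["axial_shift_label"] = sh.label
            except KeyError as exc:
                warnings.append(f"{name}/{stack}: {exc}")
        block["stacks"][stack] = sblock

    try:
        hp = helical_parameters(model)
        block["helical"] = {
            "twist_deg_per_layer": hp.twist_deg_per_layer,
            "rise_A": hp.rise_A,
            "crossover_nm": hp.crossover_nm,
            "pitch_nm": hp.pitch_nm,
            "handedness": hp.handedness,
            "rmsd_A": hp.rmsd_A,
        }
    except ValueError as exc:
        warnings.append(f"{name}: helical parameters unavailable ({exc})")
        block["helical"] = None

    block["width_nm"] = model_width(model)

    if len(model.stacks) == 2:
        try:
            block["stagger_A"] = stack_stagger(model, config.register_pair[1])
        except (ValueError, KeyError) as exc:
            warnings.append(f"{name}: stagger unavailable ({exc})")

    profile = layer_net_charge(model, ccfg)
    block["layer_net_charge_e"] = {str(k): v for k, v in profile.layer_net.items()}
    block["interior_layer_charge_e"] = profile.layer_net[central]
    asym = charge_asymmetry(model, ccfg, layer=central)
    block["charge_asymmetry"] = {
        "magnitude_eA": asym["magnitude_eA"],
        "normalized_score": asym["normalized_score"],
    }
    block["_warnings"] = warnings
    return block


def compare_fibrils(model_a: FibrilModel, model_b: FibrilModel,
                    config: CompareConfig | None = None,
                    names: tuple[str, str] = ("model_a", "model_b"),
                    ) -> ComparisonReport:
    """Analyze two fibril models under one shared configuration and
    summarize their differences."""
    config = config or CompareConfig()
    blocks = {}
    for name, model in zip(names, (model_a, model_b)):
        try:
            blocks[name] = analyze_model(model, config, name)
        except Exception as exc:
            raise RuntimeError(f"analysis of {name} failed: {exc}") from exc

    a, b = (blocks[n] for n in names)
    diffs: dict = {"sign_flips": {}, "numeric": {}}
    ha, hb = a.get("helical"), b.get("helical")
    if ha and hb:
        diffs["sign_flips"]["helical_handedness"] = ha["handedness"] != hb["handedness"]
        diffs["numeric"]["twist_deg_per_layer"] = ha["twist_deg_per_layer"] - hb["twist_deg_per_layer"]
        diffs["numeric"]["rise_A"] = ha["rise_A"] - hb["rise_A"]
        diffs["numeric"]["crossover_nm"] = ha["crossover_nm"] - hb["crossover_nm"]
    for stack in set(a["stacks"]) & set(b["stacks"]):
        sa, sb = a["stacks"][stack], b["stacks"][stack]
        if "handedness_call" in sa and "handedness_call" in sb:
            diffs["sign_flips"][f"delta_call_{stack}"] = (
                sa["handedness_call"] != sb["handedness_call"])
        for key in ("delta_mean_deg", "axial_shift_A"):
            if key in sa and key in sb:
                diffs["numeric"][f"{key}_{stack}"] = sa[key] - sb[key]
    diffs["numeric"]["interior_layer_charge_e"] = (
        a["interior_layer_charge_e"] - b["interior_layer_charge_e"])
    diffs["numeric"]["width_nm"] = a["width_nm"] - b["width_nm"]

    warnings = a.pop("_warnings", []) + b.pop("_warnings", [])
    report = ComparisonReport(
        models=blocks, differences=diffs,
        provenance={
            "inputs": {names[0]: model_a.provenance.get("source", "in-memory"),
                       names[1]: model_b.provenance.get("source", "in-memory")},
            "config": asdict(config),
            "config_hash": config.hash(),
            "package_version": __version__,
        },
        warnings=warnings)
    return report


def _flatten(prefix: str, obj, rows: list) -> None:
    if isinstance(obj, dict):
        for k, v in sorted(obj.items()):
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(obj, bool):
        rows.append((prefix, int(obj)))
    elif isinstance(obj, (int, float)):
        rows.append((prefix, obj))


def write_report(report: ComparisonReport, out_dir,
                 formats: tuple = ("json", "tsv", "markdown")) -> dict:
    """Serialize the report; JSON is canonical, TSV flattens the numeric
    fields, markdown renders a side-by-side table.  Returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if "json" in formats:
        p = out_dir / "comparison.json"
        p.write_text(report.to_json())
        paths["json"] = p
    if "tsv" in formats:
        rows: list = []
        _flatten("", {"models": report.models,
                      "differences": report.differences}, rows)
        df = pd.DataFrame(rows, columns=["field", "value"])
        p = out_dir / "comparison.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths["tsv"] = p
    if "markdown" in formats:
        p = out_dir / "comparison.md"
        p.write_text(_markdown(report))
        paths["markdown"] = p
    return paths


def _markdown(report: ComparisonReport) -> str:
    names = list(report.models)
    lines = ["# Fibril comparison", "",
             f"| quantity | {names[0]} | {names[1]} |",
             "|---|---|---|"]

    def fmt(v):
        if isinstance(v, float):
            return f"{v:.3f}"
        return str(v)

    def row(label, getter):
        vals = []
        for n in names:
            try:
                vals.append(fmt(getter(report.models[n])))
            except (KeyError, TypeError):
                vals.append("-")
        lines.append(f"| {label} | {vals[0]} | {vals[1]} |")

    row("width (nm)", lambda m: m["width_nm"])
    row("twist (deg/layer)", lambda m: m["helical"]["twist_deg_per_layer"])
    row("rise (A)", lambda m: m["helical"]["rise_A"])
    row("crossover (nm)", lambda m: m["helical"]["crossover_nm"])
    row("pitch (nm)", lambda m: m["helical"]["pitch_nm"])
    row("handedness (helical)", lambda m: m["helical"]["handedness"])
    row("interior layer charge (e)", lambda m: m["interior_layer_charge_e"])
    row("charge asymmetry score",
        lambda m: m["charge_asymmetry"]["normalized_score"])
    stacks = sorted({s for n in names for s in report.models[n]["stacks"]})
    for stack in stacks:
        row(f"stack {stack} delta mean (deg)",
            lambda m, s=stack: m["stacks"][s]["delta_mean_deg"])
        row(f"stack {stack} handedness (delta)",
            lambda m, s=stack: m["stacks"][s]["handedness_call"])
        row(f"stack {stack} strands",
            lambda m, s=stack: m["stacks"][s]["n_strands"])
        row(f"stack {stack} core range",
            lambda m, s=stack: tuple(m["stacks"][s]["core_range"]))
    lines.append("")
    lines.append(f"config hash: `{report.provenance['config_hash']}`")
    return "\n".join(lines)
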