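"""Readers and writers for observation files, VCF site ingestion and JSON
reports.

Dialects
--------
SNV observation TSV: columns ``sample_id, platform, gene, site, category``
(category one of WT/HET/MUT/NOCALL/"Low Signal"). CNV observation TSV:
``sample_id, platform, gene, region, copy_call, confidence``. Signal TSV:
``sample_id, platform, gene, site, replicate_id, wt_signal, var_signal``.
A single JSON file can hold a full observation set. VCF input is read with
pysam; panel sites are matched on the record ID (rsID or legacy alias) —
site identity is alias-based, so no genome-build liftover is involved.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import pysam

from .cnv import CnvProbeVector
from .observations import (
    Category, ObservationSet, PlatformObservation, SiteGenotype, parse_category,
)
from .panels import PlatformPanel
from .phasing import SignalPair
from .sites import Gene, ProbeRegion, UnknownSiteError, resolve_site

SCHEMA_VERSION = "1.0"


class ObservationParseError(ValueError):
    def __init__(self, path: str, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


def _rows(path: Union[str, Path]) -> list[tuple[int, list[str]]]:
    out = []
    with open(path) as fh:
        header: Optional[list[str]] = None
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = [c.strip() for c in line.rstrip("\n").split("\t")]
            if header is None:
                header = cells
                out.append((line_no, header))
            else:
                out.append((line_no, cells))
    return out


def _get_platform(obs_by_sample: dict[str, ObservationSet], sample: str,
                  gene: Gene, platform: str) -> PlatformObservation:
    obs = obs_by_sample.setdefault(sample, ObservationSet(sample, gene))
    if obs.gene is not gene:
        raise ValueError(f"sample {sample}: mixed genes in one observation set")
    if platform not in obs.platforms:
        obs.platforms[platform] = PlatformObservation(platform, gene)
    return obs.platforms[platform]


def read_observations(path: Union[str, Path]) -> dict[str, ObservationSet]:
    """Read an observation file (.json for a full set, .tsv for SNV rows)
    into observation sets keyed by sample id. Malformed rows report their
    line number; unknown site labels resolve through the alias registry."""
    path = Path(path)
    if path.suffix == ".json":
        return _read_observations_json(path)
    rows = _rows(path)
    obs: dict[str, ObservationSet] = {}
    if not rows:
        return obs
    line_no, header = rows[0]
    expected = ["sample_id", "platform", "gene", "site", "category"]
    if header != expected:
        raise ObservationParseError(str(path), line_no,
                                    f"header must be {expected}, got {header}")
    for line_no, cells in rows[1:]:
        if len(cells) != len(expected):
            raise ObservationParseError(str(path), line_no,
                                        f"expected {len(expected)} columns, "
                                        f"got {len(cells)}")
        sample, platform, gene_txt, site_label, cat_txt = cells
        try:
            gene = Gene(gene_txt)
            site = resolve_site(site_label, gene)
            category = parse_category(cat_txt)
        except (ValueError, UnknownSiteError) as exc:
            raise ObservationParseError(str(path), line_no, str(exc)) from exc
        plat = _get_platform(obs, sample, gene, platform)
        plat.snv[site.canonical_id] = category
    return obs


def read_cnv_observations(path: Union[str, Path],
                          into: Optional[dict[str, ObservationSet]] = None
                          ) -> dict[str, ObservationSet]:
    """Read CNV probe rows (sample_id, platform, gene, region, copy_call,
    confidence) into observation sets."""
    rows = _rows(path)
    obs = into if into is not None else {}
    if not rows:
        return obs
    line_no, header = rows[0]
    expected = ["sample_id", "platform", "gene", "region", "copy_call", "confidence"]
    if header != expected:
        raise ObservationParseError(str(path), line_no,
                                    f"header must be {expected}, got {header}")
    for line_no, cells in rows[1:]:
        try:
            sample, platform, gene_txt, region_txt, call_txt, conf_txt = cells
            gene = Gene(gene_txt)
            region = ProbeRegion(region_txt)
            call = int(call_txt)
            conf = float(conf_txt)
        except ValueError as exc:
            raise ObservationParseError(str(path), line_no, str(exc)) from exc
        plat = _get_platform(obs, sample, gene, platform)
        if plat.cnv is None:
            plat.cnv = CnvProbeVector({region: call}, {region: conf}, platform)
        else:
            calls = dict(plat.cnv.calls)
            confs = dict(plat.cnv.confidence)
            calls[region] = call
            confs[region] = conf
            plat.cnv = CnvProbeVector(calls, confs, platform)
    return obs


def read_signal_observations(path: Union[str, Path],
                             into: Optional[dict[str, ObservationSet]] = None
                             ) -> dict[str, ObservationSet]:
    """Read raw duplicate signal pairs (sample_id, platform, gene, site,
    replicate_id, wt_signal, var_signal)."""
    rows = _rows(path)
    obs = into if into is not None else {}
    if not rows:
        return obs
    line_no, header = rows[0]
    expected = ["sample_id", "platform", "gene", "site", "replicate_id",
                "wt_signal", "var_signal"]
    if header != expected:
        raise ObservationParseError(str(path), line_no,
                                    f"header must be {expected}, got {header}")
    for line_no, cells in rows[1:]:
        try:
            sample, platform, gene_txt, site_label, rep, wt_txt, var_txt = cells
            gene = Gene(gene_txt)
            site = resolve_site(site_label, gene)
            pair = SignalPair(float(wt_txt), float(var_txt), rep)
        except (ValueError, UnknownSiteError) as exc:
            raise ObservationParseError(str(path), line_no, str(exc)) from exc
        plat = _get_platform(obs, sample, gene, platform)
        plat.signals.setdefault(site.canonical_id, []).append(pair)
    return obs


def _obs_to_dict(obs: ObservationSet) -> dict:
    platforms = {}
    for name, plat in obs.platforms.items():
        platforms[name] = {
            "snv": {site: cat.value for site, cat in plat.snv.items()},
            "cnv": None if plat.cnv is None else {
                "calls": {r.value: c for r, c in plat.cnv.calls.items()},
                "confidence": {r.value: c for r, c in plat.cnv.confidence.items()},
            },
            "signals": {
                site: [{"wt": p.wt_signal, "var": p.var_signal,
                        "replicate_id": p.replicate_id} for p in pairs]
                for site, pairs in plat.signals.items()
            },
        }
    return {"sample_id": obs.sample_id, "gene": obs.gene.value,
            "platforms": platforms,
            "structural_constraints": sorted(obs.structural_constraints)}


def write_observations(obs_by_sample: dict[str, ObservationSet],
                       path: Union[str, Path]) -> None:
    payload = {"schema_version": SCHEMA_VERSION,
               "samples": [_obs_to_dict(o) for o in obs_by_sample.values()]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _read_observations_json(path: Path) -> dict[str, ObservationSet]:
    payload = json.loads(path.read_text())
    out: dict[str, ObservationSet] = {}
    for entry in payload.get("samples", []):
        gene = Gene(entry["gene"])
        obs = ObservationSet(entry["sample_id"], gene,
                             structural_constraints=frozenset(
                                 entry.get("structural_constraints", [])))
        for name, plat in entry.get("platforms", {}).items():
            cnv = None
            if plat.get("cnv"):
                cnv = CnvProbeVector(
                    {ProbeRegion(r): c for r, c in plat["cnv"]["calls"].items()},
                    {ProbeRegion(r): c
                     for r, c in plat["cnv"].get("confidence", {}).items()},
                    name)
            obs.platforms[name] = PlatformObservation(
                name, gene,
                {site: Category(cat) for site, cat in plat.get("snv", {}).items()},
                cnv,
                {site: [SignalPair(p["wt"], p["var"], p.get("replicate_id", ""))
                        for p in pairs]
                 for site, pairs in plat.get("signals", {}).items()})
        out[obs.sample_id] = obs
    return out


def read_vcf_sites(path: Union[str, Path], panel: PlatformPanel,
                   sample: Optional[str] = None) -> list[SiteGenotype]:
    """Extract panel-site genotypes from a single-sample VCF.

    Records are matched to panel sites by the VCF ID column (rsID or legacy
    alias). 0/0 -> WT, 0/1 -> HET, 1/1 -> MUT, missing -> NOCALL;
    off-panel records are ignored.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if len(samples) != 1 and sample is None:
        raise ValueError(f"VCF has {len(samples)} samples; pass an explicit "
                         "sample selector")
    sample = sample or samples[0]
    if sample not in samples:
        raise ValueError(f"sample {sample!r} not in VCF ({samples})")
    out = []
    seen: set[str] = set()
    for record in vcf:
        if not record.id:
            continue
        try:
            site = resolve_site(record.id, panel.gene)
        except UnknownSiteError:
            continue
        if site.canonical_id not in panel.sites_assayed or site.canonical_id in seen:
            continue
        seen.add(site.canonical_id)
        gt = record.samples[sample].get("GT")
        if gt is None or any(a is None for a in gt):
            category = Category.NOCALL
        else:
            n_alt = sum(1 for a in gt if a > 0)
            category = (Category.WT, Category.HET, Category.MUT)[min(n_alt, 2)]
        out.append(SiteGenotype(site.canonical_id, category))
    for site_id in sorted(panel.sites_assayed - seen):
        out.append(SiteGenotype(site_id, Category.NOCALL))
    return out


def write_report(results, path: Union[str, Path, IO[str]]) -> None:
    """Write a JSON call report: ranked candidates, activity/phenotype,
    consensus and concordance sections as available."""
    from .caller import ActivityResult, CandidateCall
    from .consensus import ConcordanceTable, ConsensusResult

    def encode(obj):
        if isinstance(obj, CandidateCall):
            return {"diplotype": obj.diplotype.format(),
                    "flags": sorted(obj.flags)}
        if isinstance(obj, ActivityResult):
            return {"score": obj.score, "phenotype": obj.phenotype.value}
        if isinstance(obj, ConsensusResult):
            return {"sample_id": obj.sample_id,
                    "consensus": obj.consensus.format() if obj.consensus else None,
                    "contributing_platforms": list(obj.contributing_platforms),
                    "discordant_platforms": list(obj.discordant_platforms),
                    "rationale": list(obj.rationale)}
        if isinstance(obj, ConcordanceTable):
            return {group: {platform: cell.format(obj.group_n.get(group))
                            for platform, cell in row.items()}
                    for group, row in obj.rows.items()}
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if hasattr(obj, "value") and not isinstance(obj, (int, float, str)):
            return obj.value
        return obj

    payload = {"schema_version": SCHEMA_VERSION, "results": encode(results)}
    text = json.dumps(payload, indent=2, default=str) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


@dataclasses.dataclass
class RunConfig:
    """Serializable configuration making a run reproducible."""

    gene: str = "CYP2D6"
    table_path: Optional[str] = None
    panels: tuple[str, ...] = ()
    max_units: int = 4
    phase_tolerance: float = 0.12
    seed: int = 0
    out_path: Optional[str] = None
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        data["panels"] = tuple(data.get("panels", ()))
        return cls(**data)
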