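"""Readers and writers: FASTA/GenBank root sequences, YAML run
configuration, Newick phylogenies, FASTA alignment output.

External coordinates (YAML, GenBank, reports) are 1-based inclusive;
internally everything is 0-based half-open. Conversion is centralized
here. Config parsing is strict: unknown keys are rejected so that typos
fail fast instead of silently falling back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import dendropy
import yaml
from Bio import SeqIO

from .genome import Genome, GenomeError, Orf
from .rate_model import DistributionSpec, RateModelError, SubstitutionParams
from .simulator import LogEntry, Phylogeny, TipAlignment, TreeError

PathLike = Union[str, Path]


class ConfigError(ValueError):
    pass


def to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive (start, end) -> 0-based half-open."""
    if start < 1 or end < start:
        raise ConfigError(f"invalid 1-based coordinates ({start}, {end})")
    return start - 1, end


def to_external(start: int, end: int) -> tuple[int, int]:
    """0-based half-open (start, end) -> 1-based inclusive."""
    return start + 1, end


_DIST_KEYS = {"family", "shape", "scale", "ncat", "value"}


def _parse_dist(raw: dict, where: str) -> DistributionSpec:
    if not isinstance(raw, dict):
        raise ConfigError(f"{where}: distribution must be a mapping")
    unknown = set(raw) - _DIST_KEYS
    if unknown:
        raise ConfigError(f"{where}: unknown distribution keys {sorted(unknown)}")
    try:
        return DistributionSpec(
            family=raw.get("family", "gamma"),
            shape=raw.get("shape"),
            scale=raw.get("scale", 1.0),
            ncat=raw.get("ncat", 1),
            value=raw.get("value"),
        )
    except RateModelError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


@dataclass(frozen=True)
class OrfConfig:
    """One ORF as configured: 1-based inclusive coordinate pairs."""

    name: str
    coords: tuple[tuple[int, int], ...]
    strand: str
    omega: DistributionSpec
    mu: Optional[DistributionSpec] = None

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.coords)

    def to_orf(self) -> Orf:
        segments = tuple(to_internal(s, e) for s, e in self.coords)
        return Orf(self.name, segments, self.strand,
                   omega_spec=self.omega, mu_spec=self.mu)


_CONFIG_KEYS = {"circular", "kappa", "pi", "global_rate", "mu", "orfs"}
_ORF_KEYS = {"name", "coords", "strand", "omega", "mu"}

DEFAULT_KAPPA = 0.3
DEFAULT_GLOBAL_RATE = 0.05
DEFAULT_MU = DistributionSpec(family="constant", value=1.0, ncat=1)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults applied.

    ``pi=None`` means "use the empirical frequencies of the root
    sequence".
    """

    circular: bool = False
    kappa: float = DEFAULT_KAPPA
    pi: Optional[tuple[float, float, float, float]] = None
    global_rate: float = DEFAULT_GLOBAL_RATE
    mu: DistributionSpec = DEFAULT_MU
    orfs: tuple[OrfConfig, ...] = ()

    def __post_init__(self):
        if not self.kappa > 0:
            raise ConfigError(f"kappa must be > 0, got {self.kappa}")
        if not self.global_rate > 0:
            raise ConfigError("global_rate must be > 0")
        if self.pi is not None:
            pi = tuple(float(p) for p in self.pi)
            object.__setattr__(self, "pi", pi)
            if len(pi) != 4 or any(p <= 0 for p in pi):
                raise ConfigError("pi must be 4 positive frequencies")
            if abs(sum(pi) - 1.0) > 1e-9:
                raise ConfigError(f"pi must sum to 1, got {sum(pi)}")
        for orf in self.orfs:
            if orf.length % 3 != 0 or orf.length <= 0:
                raise ConfigError(
                    f"ORF {orf.name}: length {orf.length} is not a positive "
                    "multiple of 3")
            if orf.strand not in "+-":
                raise ConfigError(f"ORF {orf.name}: strand must be '+' or '-'")
        names = [o.name for o in self.orfs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate ORF names in config")

    def substitution_params(self, sequence: str) -> SubstitutionParams:
        if self.pi is None:
            return SubstitutionParams.with_empirical_pi(
                sequence, kappa=self.kappa, global_rate=self.global_rate)
        return SubstitutionParams(kappa=self.kappa, pi=self.pi,
                                  global_rate=self.global_rate)

    def to_orfs(self) -> list[Orf]:
        return [o.to_orf() for o in self.orfs]

    def echo(self) -> dict:
        """JSON-able effective configuration, defaults included."""
        def dist(d: Optional[DistributionSpec]):
            if d is None:
                return None
            return {"family": d.family, "shape": d.shape, "scale": d.scale,
                    "ncat": d.ncat, "value": d.value}

        return {
            "circular": self.circular,
            "kappa": self.kappa,
            "pi": list(self.pi) if self.pi is not None else None,
            "global_rate": self.global_rate,
            "mu": dist(self.mu),
            "orfs": [
                {"name": o.name, "coords": [list(c) for c in o.coords],
                 "strand": o.strand, "omega": dist(o.omega),
                 "mu": dist(o.mu)}
                for o in self.orfs
            ],
        }


def read_config(path: PathLike) -> RunConfig:
    """Strictly parse a YAML run configuration; an empty file yields the
    documented defaults (linear genome, kappa 0.3, empirical pi)."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if raw is None:
        raw = {}
    return parse_config(raw)


def parse_config(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}")
    orfs = []
    for i, entry in enumerate(raw.get("orfs") or []):
        where = f"orfs[{i}]"
        if not isinstance(entry, dict):
            raise ConfigError(f"{where}: must be a mapping")
        unknown = set(entry) - _ORF_KEYS
        if unknown:
            raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
        for req in ("name", "coords", "omega"):
            if req not in entry:
                raise ConfigError(f"{where}: missing required key {req!r}")
        coords = entry["coords"]
        if (not isinstance(coords, list) or not coords
                or not all(isinstance(c, list) and len(c) == 2 for c in coords)):
            raise ConfigError(
                f"{where}: coords must be a list of [start, end] pairs")
        orfs.append(OrfConfig(
            name=str(entry["name"]),
            coords=tuple((int(s), int(e)) for s, e in coords),
            strand=str(entry.get("strand", "+")),
            omega=_parse_dist(entry["omega"], f"{where}.omega"),
            mu=(_parse_dist(entry["mu"], f"{where}.mu")
                if entry.get("mu") is not None else None),
        ))
    return RunConfig(
        circular=bool(raw.get("circular", False)),
        kappa=float(raw.get("kappa", DEFAULT_KAPPA)),
        pi=tuple(raw["pi"]) if raw.get("pi") is not None else None,
        global_rate=float(raw.get("global_rate", DEFAULT_GLOBAL_RATE)),
        mu=(_parse_dist(raw["mu"], "mu") if raw.get("mu") is not None
            else DEFAULT_MU),
        orfs=tuple(orfs),
    )


def write_config(config: RunConfig, path: PathLike) -> None:
    def dist(d: Optional[DistributionSpec]):
        if d is None:
            return None
        out = {"family": d.family, "ncat": d.ncat}
        if d.family == "constant":
            out["value"] = d.value
        else:
            out.update({"shape": d.shape, "scale": d.scale})
        return out

    doc: dict = {
        "circular": config.circular,
        "kappa": config.kappa,
        "global_rate": config.global_rate,
        "mu": dist(config.mu),
        "orfs": [
            {k: v for k, v in {
                "name": o.name,
                "coords": [list(c) for c in o.coords],
                "strand": o.strand,
                "omega": dist(o.omega),
                "mu": dist(o.mu),
            }.items() if v is not None}
            for o in config.orfs
        ],
    }
    if config.pi is not None:
        doc["pi"] = list(config.pi)
    with open(path, "w") as handle:
        yaml.safe_dump(doc, handle, sort_keys=False)


# -- sequences -------------------------------------------------------------

_PLACEHOLDER_OMEGA = DistributionSpec(family="gamma", shape=2.0, scale=0.5,
                                      ncat=4)


def _cds_to_orf_config(feature, record_length: int, index: int) -> OrfConfig:
    name = None
    for key in ("gene", "locus_tag", "protein_id", "product"):
        if key in feature.qualifiers:
            name = str(feature.qualifiers[key][0])
            break
    if not name:
        name = f"cds{index}"
    coords = tuple(
        to_external(int(part.start), int(part.end))
        for part in feature.location.parts
    )
    strand = "-" if feature.location.strand == -1 else "+"
    return OrfConfig(name=name, coords=coords, strand=strand,
                     omega=_PLACEHOLDER_OMEGA)


def read_root_sequence(path: PathLike, fmt: Optional[str] = None,
                       circular: Optional[bool] = None
                       ) -> tuple[Genome, list[OrfConfig]]:
    """Read the root sequence (FASTA or GenBank). GenBank CDS features
    (including join/complement) become candidate ORF configurations with
    placeholder omega distributions."""
    path = Path(path)
    if fmt is None:
        fmt = ("genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank")
               else "fasta")
    if fmt not in ("fasta", "genbank"):
        raise ConfigError(f"unsupported sequence format {fmt!r}")
    records = list(SeqIO.parse(str(path), fmt))
    if len(records) != 1:
        raise GenomeError(
            f"expected exactly one root sequence record, found {len(records)}")
    record = records[0]
    if circular is None:
        circular = (fmt == "genbank"
                    and record.annotations.get("topology") == "circular")
    genome = Genome(str(record.seq).upper(), is_circular=bool(circular))
    orfs: list[OrfConfig] = []
    if fmt == "genbank":
        for i, feature in enumerate(record.features):
            if feature.type == "CDS":
                orfs.append(_cds_to_orf_config(feature, genome.length, i))
    return genome, orfs


def genbank_to_config(path: PathLike) -> RunConfig:
    """Config skeleton from a GenBank record: one ORF block per CDS with
    placeholder distribution specs (the gb-to-yaml accessory)."""
    genome, orf_configs = read_root_sequence(path, fmt="genbank")
    return RunConfig(circular=genome.is_circular, orfs=tuple(orf_configs))


# -- trees -----------------------------------------------------------------

def read_tree(path: PathLike, allow_polytomy: bool = False) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises various parse errors
        raise TreeError(f"could not parse Newick tree: {exc}") from exc
    return Phylogeny(tree, allow_polytomy=allow_polytomy)


def write_tree(phylogeny: Phylogeny, path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write(phylogeny.as_newick() + "\n")


# -- alignments ------------------------------------------------------------

def write_alignment(alignment: TipAlignment, path: PathLike) -> None:
    with open(path, "w") as handle:
        for label, seq in alignment.items():
            handle.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i:i + 70] + "\n")


def read_alignment(path: PathLike) -> dict[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ConfigError(f"no sequences in alignment {path}")
    return {r.id: str(r.seq).upper() for r in records}


def write_log(log: Sequence[LogEntry], path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("branch\ttime\tposition\tfrom\tto\n")
        for entry in log:
            handle.write(
                f"{entry.branch}\t{entry.time:.6g}\t"
                f"{to_external(entry.position, entry.position)[0]}\t"
                f"{entry.from_nt}\t{entry.to_nt}\n")


def write_summary(summary: dict, path: PathLike) -> None:
    with open(path, "w") as handle:
        json.dump(summary, handle, indent=2)
        handle.write("\n")
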