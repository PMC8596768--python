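"""File formats: Hudson ms-format haplotypes, TSV tables, YAML run configs.

Multi-locus haplotype data travel in the Hudson ms dialect (``//`` block
separator, ``segsites: k``, ``positions: ...`` to 6 decimals, one 0/1 row per
haplotype); population membership goes in a sidecar TSV (sample_id, deme).
Result and manifest tables are plain TSV with ``#``-prefixed header metadata.
No binary formats anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .coalescent import LocusData
from .demography import (
    Deme,
    DemographicEvent,
    DemographicModel,
    MigrationSpec,
    ParameterPrior,
)


class MsFormatError(ValueError):
    """Malformed ms-format input; the message carries the line number."""


def write_ms(loci: Sequence[LocusData], path, *, command: str = "lsd") -> None:
    """Write loci as Hudson ms-format blocks (positions to 6 decimals)."""
    with open(path, "w") as fh:
        n = loci[0].n_samples if loci else 0
        fh.write(f"{command} {n} {len(loci)}\n\n")
        for locus in loci:
            fh.write("//\n")
            fh.write(f"segsites: {locus.n_sites}\n")
            if locus.n_sites:
                fh.write("positions: " + " ".join(f"{p:.6f}" for p in locus.positions) + "\n")
                for row in locus.haplotypes:
                    fh.write("".join("1" if v else "0" for v in row) + "\n")
            else:
                fh.write("positions:\n")
                for _ in range(locus.n_samples):
                    fh.write("\n")


def write_popmap(pop_labels: Sequence, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tdeme\n")
        for i, d in enumerate(pop_labels):
            fh.write(f"s{i}\t{d}\n")


def read_popmap(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return list(df["deme"])


def read_ms(path, pop_labels: Sequence, locus_length: int) -> list[LocusData]:
    """Parse a multi-locus ms-format file into LocusData objects.

    ``pop_labels`` (e.g. from :func:`read_popmap`) assigns a deme to each
    haplotype row; ``locus_length`` is the window length in bp (the ms format
    itself carries only relative positions).
    """
    loci: list[LocusData] = []
    n = len(pop_labels)
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        block_start = i
        i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise MsFormatError(f"line {i + 1}: expected 'segsites:' after '//'")
        try:
            s = int(lines[i].split(":", 1)[1])
        except ValueError:
            raise MsFormatError(f"line {i + 1}: unreadable segsites count") from None
        i += 1
        if s == 0:
            positions = np.empty(0)
            haps = np.zeros((n, 0), dtype=np.uint8)
            if i < len(lines) and lines[i].startswith("positions:"):
                i += 1
            while i < len(lines) and lines[i].strip() == "" and lines[i] != "":
                i += 1
        else:
            if i >= len(lines) or not lines[i].startswith("positions:"):
                raise MsFormatError(f"line {i + 1}: expected 'positions:'")
            try:
                positions = np.array([float(x) for x in lines[i].split(":", 1)[1].split()])
            except ValueError:
                raise MsFormatError(f"line {i + 1}: unreadable positions") from None
            if len(positions) != s:
                raise MsFormatError(
                    f"line {i + 1}: {len(positions)} positions for segsites {s}"
                )
            i += 1
            haps = np.zeros((n, s), dtype=np.uint8)
            for r in range(n):
                if i >= len(lines):
                    raise MsFormatError(
                        f"line {i + 1}: block at line {block_start + 1} ended after "
                        f"{r} of {n} haplotype rows"
                    )
                row = lines[i].strip()
                if len(row) != s or set(row) - {"0", "1"}:
                    raise MsFormatError(f"line {i + 1}: bad haplotype row")
                haps[r] = np.frombuffer(row.encode(), dtype=np.uint8) - ord("0")
                i += 1
        loci.append(LocusData(haps, positions, locus_length, list(pop_labels)))
    return loci


# ---------------------------------------------------------------------------
# TSV tables with '#'-prefixed metadata


def write_table(df: pd.DataFrame, path, metadata: Mapping | None = None, *, index=True) -> None:
    with open(path, "w") as fh:
        if metadata:
            fh.write("# " + json.dumps(dict(metadata)) + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path, **kwargs) -> tuple[pd.DataFrame, dict]:
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        if line.startswith("# "):
            try:
                meta = json.loads(line[2:])
            except json.JSONDecodeError:
                fh.seek(pos)
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", **kwargs)
    return df, meta


def write_manifest(genome, path, *, metadata: Mapping | None = None) -> None:
    """Locus manifest: truth labels, regime fields and pseudo-chromosome
    coordinates (0-based half-open, loci laid end to end)."""
    rows = []
    length = genome.locus_length
    for i, (_, label, regime) in enumerate(genome.loci):
        rows.append(
            {
                "locus_id": i,
                "label": label,
                "start": i * length,
                "end": (i + 1) * length,
                "s1": getattr(regime, "s1", np.nan),
                "s2": getattr(regime, "s2", np.nan),
                "t_onset": getattr(regime, "t_onset", np.nan),
                "origin": getattr(regime, "origin", ""),
            }
        )
    write_table(pd.DataFrame(rows).set_index("locus_id"), path, metadata)


# ---------------------------------------------------------------------------
# YAML run configuration


@dataclass
class RunConfig:
    """A parsed run configuration: model, priors and scan settings."""

    model: DemographicModel
    priors: list
    sample_config: dict
    locus_length: int = 5000
    n_sims: int = 50_000
    retention_fraction: float = 0.01
    pls_components: int | None = None
    grid_shape: tuple = (33, 33)
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def model_from_dict(d: Mapping) -> DemographicModel:
    demes = [
        Deme(x["id"], x["initial_size"], x.get("growth_rate", 0.0)) for x in d["demes"]
    ]
    migration = MigrationSpec(
        {(e["source"], e["dest"]): e["rate"] for e in d.get("migration", [])}
    )
    events = tuple(
        DemographicEvent(
            e["time"], e["kind"], {k: v for k, v in e.items() if k not in ("time", "kind")}
        )
        for e in d.get("events", [])
    )
    return DemographicModel(
        demes=demes,
        migration=migration,
        events=events,
        mutation_rate=d.get("mutation_rate", 0.0),
        free_parameters=tuple(d.get("free_parameters", ())),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    model = model_from_dict(raw["model"])
    priors = [
        ParameterPrior(p["name"], p.get("scale", "linear"), float(p["lower"]), float(p["upper"]))
        for p in raw.get("priors", [])
    ]
    known = {"model", "priors", "sample", "locus_length", "n_sims",
             "retention_fraction", "pls_components", "grid_shape", "seed"}
    return RunConfig(
        model=model,
        priors=priors,
        sample_config={str(k): int(v) for k, v in raw.get("sample", {}).items()},
        locus_length=int(raw.get("locus_length", 5000)),
        n_sims=int(raw.get("n_sims", 50_000)),
        retention_fraction=float(raw.get("retention_fraction", 0.01)),
        pls_components=raw.get("pls_components"),
        grid_shape=tuple(raw.get("grid_shape", (33, 33))),
        seed=raw.get("seed"),
        extras={k: v for k, v in raw.items() if k not in known},
    )
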