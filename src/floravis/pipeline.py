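"""Cultivar-level orchestration: assemble spectra, run contrasts, report.

A *cultivar dataset* maps floral parts (petal, anther, sepal, upper leaf,
or the joint anther+sepal disk) to reflectance spectra on a common grid.
``run_contrast_analysis`` computes the pairwise ΔS table for each cultivar
against its own upper-leaf spectrum as the adaptation background — the
convention for modelling a bee foraging over foliage — and returns a report
whose configuration snapshot is complete enough to re-run bit-identically.

``fetch_deposited_spectra`` retrieves an archived measurement deposit by
Zenodo DOI into a checksummed local cache; it is strictly optional and the
rest of the pipeline runs entirely on local or synthetic files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .contrast import ContrastRecord, ModelConfig, pairwise_contrast_table
from .receptors import default_bee_receptors, make_illuminant, pigment_template, ReceptorSet
from .spectra import (
    FloralPart,
    ReflectanceSpectrum,
    WavelengthGrid,
    parse_spectrum_table,
    parse_spectrum_workbook,
    resample_to_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CultivarDataset",
    "AnalysisReport",
    "assemble_dataset",
    "run_contrast_analysis",
    "fetch_deposited_spectra",
]

_ANALYSIS_GRID = WavelengthGrid.regular(300.0, 700.0, 1.0)


@dataclass(frozen=True)
class CultivarDataset:
    """All part spectra for one cultivar, aligned to a common grid."""

    cultivar: str
    spectra: dict[FloralPart, ReflectanceSpectrum]
    replicate_counts: dict[FloralPart, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("cultivar dataset has no spectra")
        grids = {id(s.grid): s.grid for s in self.spectra.values()}
        first = next(iter(self.spectra.values())).grid
        if not all(g == first for g in grids.values()):
            raise ValueError("all part spectra must share a grid")
        for part, n in self.replicate_counts.items():
            if n < 1:
                raise ValueError(f"replicate count for {part} must be >= 1")


@dataclass(frozen=True)
class AnalysisReport:
    """Per-cultivar contrast records plus the full model configuration."""

    records: list[tuple[str, ContrastRecord]]
    config: dict
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cultivar": cultivar,
                "pair": rec.pair,
                "delta_s": rec.delta_s,
                "detectable": rec.detectable,
                "config_id": rec.model_config_id,
            }
            for cultivar, rec in self.records
        ]
        return pd.DataFrame(rows, columns=["cultivar", "pair", "delta_s", "detectable", "config_id"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
        meta = Path(path).with_suffix(".config.json")
        meta.write_text(json.dumps({"config": self.config, "provenance": self.provenance}, indent=2))

    def to_excel(self, path: str | Path) -> None:
        """Spreadsheet export mirroring the per-cultivar pair layout."""
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            self.to_frame().to_excel(xl, sheet_name="contrasts", index=False)
            pd.DataFrame(sorted(self.config.items()), columns=["key", "value"]).astype(str).to_excel(
                xl, sheet_name="config", index=False
            )


def _load_part_files(paths: list[str | Path], base: Path) -> list[ReflectanceSpectrum]:
    spectra: list[ReflectanceSpectrum] = []
    for p in paths:
        path = base / str(p)
        if path.suffix.lower() in (".xlsx", ".xls"):
            spectra.extend(parse_spectrum_workbook(path))
        else:
            spectra.extend(parse_spectrum_table(path))
    return spectra


def assemble_dataset(
    manifest: dict | str | Path,
    *,
    grid: WavelengthGrid = _ANALYSIS_GRID,
) -> list[CultivarDataset]:
    """Build cultivar datasets from a manifest of labelled spectrum files.

    The manifest maps cultivar → part code → file path or list of replicate
    file paths (YAML file path accepted).  Replicate spectra for the same
    (cultivar, part) are resampled to the analysis grid and averaged
    pointwise; the replicate count is recorded.  A cultivar with fewer than
    two parts cannot enter a contrast analysis and is rejected.
    """
    base = Path(".")
    if isinstance(manifest, (str, Path)):
        import yaml

        base = Path(manifest).parent
        manifest = yaml.safe_load(Path(manifest).read_text())
    cultivars = manifest.get("cultivars", manifest)
    if not cultivars:
        raise ValueError("manifest names no cultivars")
    datasets: list[CultivarDataset] = []
    for cultivar, parts in cultivars.items():
        if len(parts) < 2:
            raise ValueError(f"cultivar {cultivar!r} has fewer than two parts")
        spectra: dict[FloralPart, ReflectanceSpectrum] = {}
        counts: dict[FloralPart, int] = {}
        for part_code, files in parts.items():
            part = FloralPart.from_code(part_code)
            file_list = files if isinstance(files, list) else [files]
            loaded = _load_part_files(file_list, base)
            if not loaded:
                raise ValueError(f"no spectra found for {cultivar}/{part_code}")
            resampled = [resample_to_grid(s, grid) for s in loaded]
            mean = np.mean([s.reflectance for s in resampled], axis=0)
            spectra[part] = ReflectanceSpectrum(
                grid=grid,
                reflectance=mean,
                label=f"{cultivar}:{part.code}",
                part=part,
                specimen_id=cultivar,
            )
            counts[part] = len(resampled)
        datasets.append(CultivarDataset(cultivar=cultivar, spectra=spectra, replicate_counts=counts))
    return datasets


def _receptors_for(config: ModelConfig, grid: WavelengthGrid) -> ReceptorSet:
    uv, blue, green = (
        pigment_template(peak, grid, beta_band=config.beta_band)
        for peak in config.receptor_peaks
    )
    return ReceptorSet(uv=uv, blue=blue, green=green)


def run_contrast_analysis(
    datasets: list[CultivarDataset],
    config: ModelConfig | None = None,
    *,
    background_spectrum: ReflectanceSpectrum | None = None,
) -> AnalysisReport:
    """Pairwise ΔS per cultivar with its own leaf as adaptation background.

    Deterministic given (datasets, config).  With ``background == "own_leaf"``
    (the default) a cultivar lacking an upper-leaf spectrum is an error named
    after the cultivar; alternatively pass a fixed reference
    ``background_spectrum``.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    config = config or ModelConfig()
    grid = next(iter(datasets[0].spectra.values())).grid
    receptors = _receptors_for(config, grid)
    ill = make_illuminant(config.illuminant, grid)
    records: list[tuple[str, ContrastRecord]] = []
    for ds in datasets:
        if config.background == "own_leaf":
            if FloralPart.LEAF_UPPER not in ds.spectra:
                raise ValueError(
                    f"cultivar {ds.cultivar!r} lacks an upper-leaf spectrum for own-leaf adaptation"
                )
            background = ds.spectra[FloralPart.LEAF_UPPER]
        else:
            if background_spectrum is None:
                raise ValueError("fixed background requested but no background_spectrum given")
            background = resample_to_grid(background_spectrum, grid)
        for rec in pairwise_contrast_table(ds.spectra, config, receptors, ill, background):
            logger.info("%s %s: delta_s=%.3f detectable=%s", ds.cultivar, rec.pair, rec.delta_s, rec.detectable)
            records.append((ds.cultivar, rec))
    provenance = {
        "package_version": _pkg_version,
        "cultivars": [ds.cultivar for ds in datasets],
        "replicates": {
            ds.cultivar: {p.code: n for p, n in ds.replicate_counts.items()} for ds in datasets
        },
    }
    return AnalysisReport(records=records, config=config.snapshot(), provenance=provenance)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def fetch_deposited_spectra(doi: str, cache_dir: str | Path) -> list[Path]:
    """Fetch a Zenodo deposit's files into a checksummed local cache.

    On a cache hit (all files present with matching recorded checksums) no
    network access happens.  On network failure the error message points at
    the synthetic generator as the offline fallback.  A checksum mismatch
    invalidates the cache entry rather than silently reusing it.
    """
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    checksums_path = cache / "checksums.json"
    if checksums_path.exists():
        recorded = json.loads(checksums_path.read_text())
        files = [cache / name for name in recorded]
        if all(f.exists() for f in files):
            mismatched = [f.name for f in files if _sha256(f) != recorded[f.name]]
            if mismatched:
                raise ValueError(f"cached files fail checksum verification: {mismatched}")
            logger.info("cache hit for %s (%d files)", doi, len(files))
            return files
    record_id = doi.rsplit(".", 1)[-1].lstrip("zenodo")
    if not record_id.isdigit():
        raise ValueError(f"cannot extract a Zenodo record id from DOI {doi!r}")
    api = f"https://zenodo.org/api/records/{record_id}"
    try:
        with urllib.request.urlopen(api, timeout=30) as resp:
            meta = json.loads(resp.read())
        out: list[Path] = []
        sums: dict[str, str] = {}
        for entry in meta["files"]:
            name = entry.get("key") or entry["filename"]
            url = entry["links"].get("self") or entry["links"]["download"]
            dest = cache / name
            urllib.request.urlretrieve(url, dest)
            sums[name] = _sha256(dest)
            out.append(dest)
    except Exception as exc:  # noqa: BLE001 - any failure means no partial cache
        for stray in cache.glob("*"):
            if stray != checksums_path:
                stray.unlink(missing_ok=True)
        raise RuntimeError(
            f"could not fetch deposit {doi!r} ({exc}); "
            "use the synthetic generator (floravis synth demo) for offline work"
        ) from exc
    checksums_path.write_text(json.dumps(sums, indent=2))
    return out
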