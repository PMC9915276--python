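"""Packaged instrument sets: COVID-19 phenotypes vs ME/CFS.

Three harmonized instrument sets ship with the package, one per COVID-19
exposure phenotype from the COVID-19 Host Genetics Initiative GWAS meta-
analyses (UK Biobank excluded), with outcome associations from a UK Biobank
ME/CFS GWAS (2,076 cases / 460,857 controls):

* ``severity`` — 20 SNPs (very severe respiratory COVID-19 vs population);
* ``hospitalization`` — 24 SNPs (hospitalized COVID-19 vs population);
* ``susceptibility`` — 13 SNPs (reported infection vs population).

Each TSV carries per-SNP exposure and outcome betas, SEs and p-values,
already aligned to the same effect allele and LD-clumped (p < 5e-8,
r² < 0.001, 10,000 kb), so they drop straight into the estimators.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .summary_data import HarmonizedSet

FIXTURE_NAMES = ("severity", "hospitalization", "susceptibility")

#: Exposure GWAS sample sizes (cases + controls) for instrument-strength stats.
EXPOSURE_N = {"severity": 743_167, "hospitalization": 1_965_329, "susceptibility": 2_501_486}
OUTCOME_N = 462_933

_FILES = {
    "severity": "covid_severity.tsv",
    "hospitalization": "covid_hospitalization.tsv",
    "susceptibility": "covid_susceptibility.tsv",
}

_SHA256 = {
    "severity": "62b779d0d91b2ab00d54081090cc9bf1c6a502694f8740904902c67680db67a5",
    "hospitalization": "7b9688d0f6696d6239a6cc66b52ed58aa760eae96122eead9eed256ba8e6519a",
    "susceptibility": "4f91f62698a9ae939ef80e4d0b6d28831e7fad18b037a919fe8c86a2eb32c0cd",
}


def load_instruments(name: str) -> HarmonizedSet:
    """Load one packaged instrument set as a :class:`HarmonizedSet`.

    The shipped file is checksum-verified before parsing; a corrupted
    installation raises rather than silently analysing altered numbers.
    """
    if name not in _FILES:
        raise KeyError(f"unknown instrument set {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("tsmr.data").joinpath(_FILES[name])
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _SHA256[name]:
        raise RuntimeError(
            f"fixture {name!r} failed its checksum ({digest[:12]}…); reinstall the package"
        )
    import io

    df = pd.read_csv(io.BytesIO(raw), sep="\t")
    return HarmonizedSet(
        exposure_name=f"COVID-19 {name}",
        outcome_name="ME/CFS",
        records=df,
        provenance=f"packaged instrument set '{name}' ({len(df)} SNPs)",
    )


def load_all() -> dict[str, HarmonizedSet]:
    """All three packaged instrument sets, keyed by exposure name."""
    return {name: load_instruments(name) for name in FIXTURE_NAMES}
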