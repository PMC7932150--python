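"""Packaged data fixtures (plain-text TSV/YAML)."""

from importlib import resources


def fixture_path(name: str):
    """Filesystem path to a packaged fixture file."""
    return resources.files(__package__) / name


def load_taxon_ledger_config() -> dict:
    """Parsed species registry + ledger rules fixture."""
    import yaml

    with fixture_path("taxon_ledger.yaml").open(encoding="utf-8") as fh:
        return yaml.safe_load(fh)
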