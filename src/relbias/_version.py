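"""Version string, kept library-independent for output provenance headers."""

__version__ = "0.1.0"


def version_line() -> str:
    return f"relbias {__version__}"
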