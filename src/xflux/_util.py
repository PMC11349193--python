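from pathlib import Path


def read_text_or_str(source) -> str:
    """Return file contents if ``source`` is an existing path, else ``str(source)``.

    Long inline YAML strings would make ``Path.is_file`` raise OSError
    (name too long); those are treated as inline text.
    """
    if isinstance(source, Path):
        return source.read_text()
    try:
        p = Path(str(source))
        if p.is_file():
            return p.read_text()
    except OSError:
        pass
    return str(source)
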