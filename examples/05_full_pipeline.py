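"""Run every stage end-to-end on the tiny fixture and list the outputs.

synth -> features -> relevance -> prediction -> negative selection,
writing each stage's TSV under ./pipeline_out.  Running it twice with the
same seed produces byte-identical files.
"""

from pathlib import Path

from netnegsel import run_pipeline

out = run_pipeline(Path("pipeline_out"), fixture="tiny")
for p in sorted(out.rglob("*")):
    if p.is_file():
        print(f"{p.relative_to(out)}  ({p.stat().st_size} bytes)")
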