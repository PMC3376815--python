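"""Regenerate the packaged Country X fixture YAML files from their builders.

Run from the repository root after changing the fixture skeletons:

    python scripts/build_fixture_data.py

The packaged files are canonical; a test asserts they match the builders.
"""

from pathlib import Path

from ihrcost.fixtures import build_country_x_coarse, build_country_x_fine
from ihrcost.template_io import write_template

DATA = Path(__file__).resolve().parent.parent / "src" / "ihrcost" / "data"


def main() -> None:
    DATA.mkdir(exist_ok=True)
    for builder, name in ((build_country_x_coarse, "country_x_coarse"),
                          (build_country_x_fine, "country_x_fine")):
        path = DATA / f"{name}.yaml"
        write_template(builder(), path)
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
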