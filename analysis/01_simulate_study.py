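#!/usr/bin/env python
"""Stage 1: generate the synthetic irrigation study.

Seven NaOCl-irrigated roots are sampled at 18 equidistant points (50 um)
per quadrant from the canal wall towards the CDJ; one water-irrigated
control root is sampled at 6 points (150 um) in the buccal quadrant.
Reference-point indentation records (18 sites per tooth) accompany the
spectra. Raw spectra are bulky and deterministic, so they are written to
scratch/ and can always be regenerated from the seed; the manifest and
indentation tables are kept under results/data/.
"""

from pathlib import Path

from ramident.io import write_manifest, write_spectrum
from ramident.synthetic import generate_study

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "raman_spectra"
DATA = ROOT / "results" / "data"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    DATA.mkdir(parents=True, exist_ok=True)

    spectra, manifest, indentation = generate_study(seed=SEED)
    for s, fname in zip(spectra, manifest["file"]):
        write_spectrum(s, SCRATCH / fname)
    write_manifest(manifest, DATA / "manifest.csv")
    indentation.to_csv(DATA / "indentation.csv", index=False)

    n_naocl = (manifest["treatment"] == "naocl").sum()
    n_ctrl = (manifest["treatment"] == "control").sum()
    print(f"seed {SEED}: wrote {len(spectra)} spectra to {SCRATCH}")
    print(f"  NaOCl transect points: {n_naocl} "
          f"({manifest[manifest.treatment == 'naocl'].tooth_id.nunique()} teeth x "
          f"4 quadrants x 18 points)")
    print(f"  control transect points: {n_ctrl}")
    print(f"  indentation records: {len(indentation)} "
          f"({indentation.tooth_id.nunique()} teeth)")


if __name__ == "__main__":
    main()
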