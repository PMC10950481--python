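"""Regenerate the bundled synthetic element library.

The shipped matrices are synthetic reconstructions from the published
consensus of each core promoter element (the experimentally derived
matrices of existing web tools are external downloads and are not
redistributed). Each element's default cutoff is the equal-error-rate
operating point of the log-likelihood detector at GC 0.5 (pseudocount
1e-3): the score at which the miss rate on draws from the motif model
equals the per-window false-positive rate on the background, floored to
one decimal. Both error curves are computed exactly by per-column
convolution.

Run from the repository root:

    python scripts/build_default_library.py
"""

from __future__ import annotations

import math
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from corescan.element_library import CompositeRule, ElementDefinition, Library  # noqa: E402
from corescan.motif_model import (  # noqa: E402
    background_from_gc,
    equal_error_cutoff,
    pwm_from_consensus,
    to_scoring_matrix,
    write_pwm,
)

# name, consensus (IUPAC), anchor_offset, category, default_search_window, citation
ELEMENTS = [
    ("TATA", "TATAWAAR", 0, "upstream", (-33, -23), "Bucher 1990 (J Mol Biol 212:563)"),
    ("BREu", "SSRCGCC", 0, "upstream", (-40, -30), "Lagrange et al. 1998"),
    ("BREd", "RTDKKKK", 0, "upstream", (-26, -16), "Deng & Roberts 2005"),
    ("Inr", "YYANWYY", 2, "initiator", (-5, 2), "Javahery et al. 1994; Lo & Smale 1996"),
    ("BBCA+1BW", "BBCABW", 3, "initiator", (-6, 1), "Vo ngoc et al. 2017 (human Inr consensus)"),
    ("dInr", "TCAGTY", 2, "initiator", (-5, 2), "Hultmark et al. 1986; Purnell et al. 1994"),
    ("TCT", "YYCTTTYY", 2, "initiator", (-5, 2), "Parry et al. 2010 (human ribosomal protein genes)"),
    ("dTCT", "YYCTTTYY", 2, "initiator", (-5, 2), "Parry et al. 2010 (Drosophila)"),
    ("DPE", "RGWYVT", 0, "downstream", (26, 34), "Burke & Kadonaga 1996; Kutach & Kadonaga 2000"),
    ("MTE", "CSARCSSAACGS", 0, "downstream", (16, 24), "Lim et al. 2004"),
    ("Bridge", "CSARCNNNNNRGWYVT", 0, "downstream", (16, 22), "Theisen et al. 2010 (MTE/DPE bridge)"),
    ("PB", "KCGRWCG", 0, "pausing", (18, 34), "Hendrix et al. 2008 (pause button)"),
    ("Motif1", "YGGTCACACTR", 0, "pausing", (-12, 4), "Ohler et al. 2002 motif 1; Li & Gilmour 2013 (M1BP)"),
    ("GAGA", "GAGAGAG", 0, "pausing", None, "GAGA factor binding site, after CIS-BP M5247 v1.02"),
]

RULES = [
    CompositeRule(dependent="DPE", anchor="dInr", spacing_window=(28, 33)),
    CompositeRule(dependent="MTE", anchor="dInr", spacing_window=(18, 22)),
    CompositeRule(dependent="Bridge", anchor="dInr", spacing_window=(18, 20)),
]

CUTOFF_GC = 0.5  # background at which the equal-error cutoffs are computed


def main() -> None:
    out_dir = Path(__file__).resolve().parents[1] / "src" / "corescan" / "data" / "synthetic_library"
    out_dir.mkdir(parents=True, exist_ok=True)
    bg = background_from_gc(CUTOFF_GC)
    definitions = []
    for name, consensus, anchor, category, window, citation in ELEMENTS:
        pwm = pwm_from_consensus(name, consensus, anchor_offset=anchor)
        cutoff = math.floor(equal_error_cutoff(pwm, bg) * 10) / 10.0
        pwm = pwm_from_consensus(name, consensus, anchor_offset=anchor, cutoff=cutoff)
        sm = to_scoring_matrix(pwm, bg)
        definitions.append(
            ElementDefinition(
                name=name,
                pwm=pwm,
                category=category,
                default_search_window=window,
                citation=citation,
            )
        )
        print(f"{name:10s} L={pwm.length:2d} max={sm.max_score:7.3f} cutoff={cutoff:6.1f}")
    library = Library(elements=definitions, rules=RULES)
    for el in library:
        meta = {"category": el.category}
        if el.default_search_window is not None:
            lo, hi = el.default_search_window
            meta["window"] = f"{lo}:{hi}"
        if el.citation:
            meta["citation"] = el.citation
        write_pwm(el.pwm, out_dir / f"{el.name}.synthetic.pwm", extra_meta=meta)
    import yaml

    with open(out_dir / "rules.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "composite_rules": [
                    {
                        "dependent": r.dependent,
                        "anchor": r.anchor,
                        "spacing_window": list(r.spacing_window),
                    }
                    for r in RULES
                ]
            },
            fh,
            sort_keys=False,
        )
    print(f"wrote {len(definitions)} PWM files + rules.yaml to {out_dir}")


if __name__ == "__main__":
    main()
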