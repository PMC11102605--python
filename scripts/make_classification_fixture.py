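"""Regenerate the bundled synthetic classification fixture.

Builds src/cmuquant/data/classification_fixture.csv: a deterministic
synthetic stand-in for a literature-curated classification of an 856-taxon
plaque survey (213 oral species, 257 extraoral contaminants, 386
unknown/unclassified), with clinical-category and selective-media marginal
counts matching the published survey it emulates.  A small curated head of
well-known oral taxa carries realistic assignments; the remainder are
synthetic placeholder taxa filled in round-robin so every marginal count is
exact.  No randomness is involved.
"""

import csv
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "cmuquant" / "data" / "classification_fixture.csv"

CATEGORY_TOTALS = {
    "commensal": 138,
    "gingivitis": 32,
    "periodontitis": 55,
    "malodor": 29,
    "caries": 23,
    "oral_health_associated": 9,
    "opportunistic_pathogen": 85,
    "infectious_pathogen": 23,
}
MEDIA_TOTALS = {
    "total_anaerobe": 153,
    "fusobacteria": 3,
    "streptococci": 22,
    "actinomyces": 2,
}
N_ORAL, N_CONTAMINANT, N_UNKNOWN = 213, 257, 386

STREPTOCOCCI = [
    "Streptococcus mutans", "Streptococcus sobrinus", "Streptococcus mitis",
    "Streptococcus oralis", "Streptococcus sanguinis", "Streptococcus gordonii",
    "Streptococcus salivarius", "Streptococcus anginosus", "Streptococcus intermedius",
    "Streptococcus constellatus", "Streptococcus parasanguinis", "Streptococcus cristatus",
    "Streptococcus infantis", "Streptococcus australis", "Streptococcus vestibularis",
    "Streptococcus peroris", "Streptococcus sinensis", "Streptococcus downei",
    "Streptococcus dentisani", "Streptococcus oligofermentans", "Streptococcus agalactiae",
    "Streptococcus pneumoniae",
]

# (name, categories, media_groups) — realistic assignments for well-known taxa
CURATED = [
    ("Fusobacterium nucleatum", ["gingivitis", "periodontitis", "malodor"],
     ["total_anaerobe", "fusobacteria"]),
    ("Fusobacterium periodonticum", ["gingivitis", "malodor"],
     ["total_anaerobe", "fusobacteria"]),
    ("Fusobacterium naviforme", ["opportunistic_pathogen"],
     ["total_anaerobe", "fusobacteria"]),
    ("Actinomyces naeslundii", ["commensal", "caries"], ["actinomyces"]),
    ("Actinomyces israelii", ["opportunistic_pathogen"], ["actinomyces"]),
    ("Rothia dentocariosa", ["commensal"], []),
    ("Prevotella loescheii", ["gingivitis", "malodor"], ["total_anaerobe"]),
    ("Prevotella intermedia", ["gingivitis", "periodontitis"], ["total_anaerobe"]),
    ("Prevotella melaninogenica", ["malodor"], ["total_anaerobe"]),
    ("Porphyromonas gingivalis", ["periodontitis", "malodor"], ["total_anaerobe"]),
    ("Tannerella forsythia", ["periodontitis"], ["total_anaerobe"]),
    ("Treponema denticola", ["periodontitis"], ["total_anaerobe"]),
    ("Treponema socranskii", ["periodontitis"], ["total_anaerobe"]),
    ("Veillonella parvula", ["commensal"], ["total_anaerobe"]),
    ("Solobacterium moorei", ["malodor"], ["total_anaerobe"]),
    ("Aggregatibacter actinomycetemcomitans", ["periodontitis", "infectious_pathogen"], []),
    ("Eikenella corrodens", ["gingivitis", "opportunistic_pathogen"], []),
    ("Gemella morbillorum", ["opportunistic_pathogen"], []),
    ("Neisseria mucosa", ["commensal"], []),
    ("Neisseria meningitidis", ["infectious_pathogen"], []),
    ("Cutibacterium acnes", ["opportunistic_pathogen"], []),
    ("Abiotrophia defectiva", ["commensal", "opportunistic_pathogen"], []),
    ("Lactobacillus fermentum", ["caries"], []),
    ("Haemophilus parainfluenzae", ["commensal"], []),
] + [
    ("Streptococcus mutans", ["caries"], ["streptococci"]),
    ("Streptococcus sobrinus", ["caries"], ["streptococci"]),
    ("Streptococcus mitis", ["commensal", "oral_health_associated"], ["streptococci"]),
    ("Streptococcus oralis", ["commensal"], ["streptococci"]),
    ("Streptococcus sanguinis", ["commensal", "oral_health_associated"], ["streptococci"]),
    ("Streptococcus gordonii", ["commensal"], ["streptococci"]),
    ("Streptococcus salivarius", ["commensal", "oral_health_associated"], ["streptococci"]),
    ("Streptococcus pneumoniae", ["infectious_pathogen"], ["streptococci"]),
    ("Streptococcus agalactiae", ["infectious_pathogen"], ["streptococci"]),
] + [
    (name, ["commensal"], ["streptococci"])
    for name in STREPTOCOCCI
    if name not in {
        "Streptococcus mutans", "Streptococcus sobrinus", "Streptococcus mitis",
        "Streptococcus oralis", "Streptococcus sanguinis", "Streptococcus gordonii",
        "Streptococcus salivarius", "Streptococcus pneumoniae", "Streptococcus agalactiae",
    }
]

CONTAMINANT_HEAD = [
    "Staphylococcus epidermidis", "Staphylococcus hominis", "Ralstonia pickettii",
    "Bradyrhizobium japonicum", "Methylobacterium radiotolerans", "Sphingomonas paucimobilis",
]


def build_rows():
    names = [c[0] for c in CURATED]
    assert len(set(names)) == len(names)

    cat_quota = dict(CATEGORY_TOTALS)
    media_quota = dict(MEDIA_TOTALS)
    for _, cats, media in CURATED:
        for c in cats:
            cat_quota[c] -= 1
        for m in media:
            media_quota[m] -= 1
    assert all(q >= 0 for q in cat_quota.values()), cat_quota
    assert all(q >= 0 for q in media_quota.values()), media_quota
    assert media_quota["fusobacteria"] == 0
    assert media_quota["streptococci"] == 0
    assert media_quota["actinomyces"] == 0

    n_syn = N_ORAL - len(CURATED)
    syn_names = [f"Oral taxon {i:03d}" for i in range(1, n_syn + 1)]
    syn_cats = [set() for _ in syn_names]
    syn_media = [set() for _ in syn_names]

    # round-robin fill keeps every marginal exact and spreads overlap evenly
    idx = 0
    for cat in sorted(cat_quota, key=cat_quota.get, reverse=True):
        remaining = cat_quota[cat]
        while remaining > 0:
            if cat not in syn_cats[idx % n_syn]:
                syn_cats[idx % n_syn].add(cat)
                remaining -= 1
            idx += 1
    j = 0
    remaining = media_quota["total_anaerobe"]
    while remaining > 0:
        syn_media[j % n_syn].add("total_anaerobe")
        remaining -= 1
        j += 1

    rows = []
    for name, cats, media in CURATED:
        rows.append((name, "oral", ";".join(sorted(cats)), ";".join(sorted(media))))
    for name, cats, media in zip(syn_names, syn_cats, syn_media):
        rows.append((name, "oral", ";".join(sorted(cats)), ";".join(sorted(media))))
    for i in range(N_CONTAMINANT):
        name = (CONTAMINANT_HEAD[i] if i < len(CONTAMINANT_HEAD)
                else f"Environmental taxon {i - len(CONTAMINANT_HEAD) + 1:03d}")
        rows.append((name, "extraoral_contaminant", "", ""))
    for i in range(1, N_UNKNOWN + 1):
        rows.append((f"Unclassified taxon {i:03d}", "unknown_unclassified", "", ""))
    return rows


def main():
    rows = build_rows()
    assert len(rows) == N_ORAL + N_CONTAMINANT + N_UNKNOWN
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["taxon_id", "source", "categories", "media_groups"])
        writer.writerows(rows)
    print(f"wrote {OUT} ({len(rows)} taxa)")


if __name__ == "__main__":
    main()
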