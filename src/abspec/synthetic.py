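"""Seeded generator of synthetic articles with known specificity gold labels.

No machine-readable annotated corpus accompanies the original antibody-watch
style studies, so this module manufactures one: each article has a Materials
and Methods section whose sentences register antibodies (a clone token, a
catalog number and an ``RRID:AB_<digits>`` identifier) and a Results section
with specificity statements instantiated from class-specific templates built
around the three cue families (``specific``, ``background staining``,
``cross-reactiv``).  Gold classes and gold statement-to-RRID links are recorded
at generation time, so extraction, classification, linking and the end-to-end
pipeline can all be scored exactly.

The template bank deliberately includes hard cases — "non-specific antibodies"
used as blocking controls in positive statements, double negation, and
described-but-unresolved specificity tests for the neutral class — so that a
classifier cannot win on a single cue word.  Class mix defaults to
(0.10, 0.10, 0.80) and the within-article pairing yields roughly a 15% "yes"
link rate, matching the skew of curated corpora in this domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
from xml.sax.saxutils import escape

import numpy as np

from .documents import Document, Section
from .encoding import AspectInstance, HashTokenizer, build_input
from .snippets import (
    extract_rrid_snippets,
    extract_spec_snippets,
    filter_antibody_snippets,
    find_antibody_mentions,
)
from .linking import SnippetPair

__all__ = [
    "CorpusSpec",
    "Antibody",
    "GoldArticle",
    "DatasetBundle",
    "generate_corpus",
    "render_article",
    "corpus_to_datasets",
    "CLASS_TEMPLATES",
]

CLASSES = ("nonspecific", "neutral", "specific")

# ---------------------------------------------------------------------------
# Template bank
# ---------------------------------------------------------------------------

CLASS_TEMPLATES: dict[str, tuple[str, ...]] = {
    "nonspecific": (
        "Some non-specific bands were detected at ~55 kDa in both wild-type and mutant lysates probed with the {clone} antibody.",
        "Five out of six commonly used anti-{target} antibodies, including {clone}, tested on knockout mouse tissue in immunoblots were non-specific.",
        "The {clone} antibody produced considerable background staining in sections from {target}-null animals.",
        "We observed substantial cross-reactivity of the {clone} antibody with unrelated antigens on the protein array.",
        "Staining with the {clone} antibody persisted in knockout tissue, suggesting that the signal is not specific for {target}.",
        "A caveat is that the affinity of the {clone} antibody for individual {target} isoforms was unknown and some bands may reflect cross-reactive binding.",
    ),
    "specific": (
        "Our {clone} antibody is specific, as each immunizing peptide blocked the corresponding immunoreactivity.",
        "Omitting the {clone} primary antibody in negative controls did not demonstrate nonspecific binding on adjacent sections.",
        "Lysates were pre-cleared with non-specific antibodies to remove contaminating proteins before immunoprecipitation with {clone}.",
        "Immunolabeling with the {clone} antibody was abolished in {target} knockout tissue, confirming that the signal is specific.",
        "A nonspecific control antibody gave no signal, whereas the {clone} antibody labeled only the expected {target} band.",
        "No background staining was observed with the {clone} antibody in control sections lacking {target}.",
    ),
    "neutral": (
        "To confirm specificity of the {clone} monoclonal antibody, an enzyme-linked immunosorbent assay was performed.",
        "Probing protein arrays with antibodies such as {clone} allows the assessment of their specificity and cross-reactivity across many potential antigens.",
        "The specificity of each antibody, including {clone}, was assessed as described previously.",
        "We designed a series of experiments to test whether the {clone} antibody is specific for {target}.",
        "Antibody specificity for {clone} was evaluated by immunoblotting against recombinant {target} protein.",
    ),
}

RRID_TEMPLATES: tuple[str, ...] = (
    "Purified anti-{target} antibody ({clone}) (Cat. No. {cat}; RRID:{rrid}) was obtained from {vendor}.",
    "The monoclonal {clone} antibody against {target} (catalog {cat}, RRID:{rrid}) was purchased from {vendor}.",
    "Rabbit polyclonal anti-{target} ({clone}, {vendor}, Cat. No. {cat}, RRID:{rrid}) was used for immunostaining.",
)

# Split at RRID boundaries must leave exactly one clone token per sub-string,
# so the second clone is named after its own RRID.
RRID_PAIR_TEMPLATE = (
    "The {clone1} antibody (RRID:{rrid1}) and a second antibody "
    "(RRID:{rrid2}, clone {clone2}) were used for double labeling."
)

FILLER_SENTENCES: tuple[str, ...] = (
    "Sections were incubated overnight at four degrees in blocking buffer.",
    "Samples were washed three times in phosphate buffered saline.",
    "Images were acquired on a confocal microscope at constant gain.",
    "Protein concentrations were determined by a standard colorimetric assay.",
    "Membranes were exposed to film for one minute before development.",
    "Tissue was fixed in paraformaldehyde and embedded in paraffin.",
    "Band intensities were quantified with open source image software.",
    "All experiments were repeated at least three times with similar results.",
    "Mice were housed under a standard light cycle with food available.",
    "Statistical comparisons used analysis of variance followed by post hoc tests.",
)

VENDORS: tuple[str, ...] = ("Novagenix", "Protheon", "Immunora", "Bindwell", "Clonarta")

_TARGET_STEMS: tuple[str, ...] = (
    "Panx", "Shank", "Grm", "Nlgn", "Dlg", "Sirt", "Trpv", "Cav", "Gfap", "Olig",
)


# ---------------------------------------------------------------------------
# Specification and gold structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusSpec:
    """Generation parameters; the defaults state the emulated study conditions."""

    n_articles: int = 50
    antibodies_per_article: tuple[int, int] = (4, 9)
    statements_per_article: tuple[int, int] = (2, 4)
    class_mix: tuple[float, float, float] = (0.10, 0.10, 0.80)
    link_prevalence: float = 0.15
    distractor_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 1:
            raise ValueError("n_articles must be positive")
        if any(p < 0 for p in self.class_mix) or abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must be non-negative and sum to 1")
        if not 0 <= self.link_prevalence <= 1:
            raise ValueError("link_prevalence must be in [0, 1]")
        if not 0 <= self.distractor_rate <= 1:
            raise ValueError("distractor_rate must be in [0, 1]")
        lo, hi = self.antibodies_per_article
        if lo < 0 or hi < lo:
            raise ValueError("antibodies_per_article must be a valid range")


@dataclass(frozen=True)
class Antibody:
    clone: str
    target: str
    rrid: str
    catalog: str
    vendor: str


@dataclass(frozen=True)
class GoldStatement:
    text: str
    label: str
    clone: str           # clone token the statement talks about
    antibody_index: int  # -1 for distractors (clone not registered in the article)
    placement: str       # "body" or "legend"


@dataclass
class GoldArticle:
    document: Document
    antibodies: list[Antibody]
    gold_spec: list[GoldStatement]
    gold_rrid: list[tuple[str, str]]         # (sentence text, rrid)
    gold_links: set[tuple[int, str]] = field(default_factory=set)

    @property
    def doc_id(self) -> str:
        return self.document.doc_id


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _new_clone(rng: np.random.Generator, used: set[str]) -> str:
    letters = "ABCDEFGHJKLMNPRSTUVWXYZ"
    while True:
        clone = f"{rng.integers(1, 10)}{letters[rng.integers(0, len(letters))]}{rng.integers(10, 100)}"
        if clone not in used:
            used.add(clone)
            return clone


def _new_target(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        target = f"{_TARGET_STEMS[rng.integers(0, len(_TARGET_STEMS))]}{rng.integers(1, 30)}"
        if target not in used:
            used.add(target)
            return target


def _new_rrid(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        rrid = f"AB_{rng.integers(10**6, 10**7)}"
        if rrid not in used:
            used.add(rrid)
            return rrid


def _filler(rng: np.random.Generator) -> str:
    return FILLER_SENTENCES[rng.integers(0, len(FILLER_SENTENCES))]


def generate_corpus(spec: CorpusSpec) -> list[GoldArticle]:
    """Generate a deterministic gold-annotated corpus from a :class:`CorpusSpec`."""
    rng = np.random.default_rng(spec.seed)
    used_clones: set[str] = set()
    used_rrids: set[str] = set()
    articles: list[GoldArticle] = []
    for art_i in range(spec.n_articles):
        doc_id = f"SYN{art_i:05d}"
        used_targets: set[str] = set()
        n_ab = int(rng.integers(spec.antibodies_per_article[0], spec.antibodies_per_article[1] + 1))
        antibodies = [
            Antibody(
                clone=_new_clone(rng, used_clones),
                target=_new_target(rng, used_targets),
                rrid=_new_rrid(rng, used_rrids),
                catalog=str(rng.integers(10**5, 10**6)),
                vendor=VENDORS[rng.integers(0, len(VENDORS))],
            )
            for _ in range(n_ab)
        ]

        # --- Materials and Methods: register every antibody exactly once ---
        mm_paragraphs: list[str] = []
        gold_rrid: list[tuple[str, str]] = []
        queue = list(range(n_ab))
        while queue:
            style = rng.random()
            if style < 0.15 and len(queue) >= 2:
                # two RRIDs inside one sentence: exercises sub-string splitting
                i, j = queue.pop(0), queue.pop(0)
                s = RRID_PAIR_TEMPLATE.format(
                    clone1=antibodies[i].clone, rrid1=antibodies[i].rrid,
                    clone2=antibodies[j].clone, rrid2=antibodies[j].rrid,
                )
                mm_paragraphs.append(" ".join([_filler(rng), s, _filler(rng)]))
                gold_rrid.append((s, antibodies[i].rrid))
                gold_rrid.append((s, antibodies[j].rrid))
            elif style < 0.40 and len(queue) >= 2:
                # two adjacent single-RRID sentences: exercises neighbor exclusion
                i, j = queue.pop(0), queue.pop(0)
                s1 = _rrid_sentence(rng, antibodies[i])
                s2 = _rrid_sentence(rng, antibodies[j])
                mm_paragraphs.append(" ".join([_filler(rng), s1, s2, _filler(rng)]))
                gold_rrid.append((s1, antibodies[i].rrid))
                gold_rrid.append((s2, antibodies[j].rrid))
            else:
                i = queue.pop(0)
                s = _rrid_sentence(rng, antibodies[i])
                mm_paragraphs.append(" ".join([_filler(rng), s, _filler(rng)]))
                gold_rrid.append((s, antibodies[i].rrid))

        # --- Results: specificity statements with gold classes and links ---
        n_stmt = int(rng.integers(spec.statements_per_article[0], spec.statements_per_article[1] + 1))
        gold_spec: list[GoldStatement] = []
        gold_links: set[tuple[int, str]] = set()
        body_paragraphs: list[str] = []
        legend_sections: list[Section] = []
        used_texts: set[str] = set()
        for k in range(n_stmt):
            label = CLASSES[int(rng.choice(3, p=spec.class_mix))]
            is_distractor = rng.random() < spec.distractor_rate
            if is_distractor or not antibodies:
                clone = _new_clone(rng, used_clones)
                target = _new_target(rng, used_targets)
                ab_index = -1
            else:
                ab_index = int(rng.integers(0, n_ab))
                clone = antibodies[ab_index].clone
                target = antibodies[ab_index].target
            bank = CLASS_TEMPLATES[label]
            # statement texts stay unique within an article so snippets map
            # back to exactly one planted statement
            text = bank[int(rng.integers(0, len(bank)))].format(clone=clone, target=target)
            while text in used_texts:
                text = bank[int(rng.integers(0, len(bank)))].format(clone=clone, target=target)
            used_texts.add(text)
            placement = "legend" if rng.random() < 0.15 else "body"
            gold_spec.append(
                GoldStatement(
                    text=text, label=label, clone=clone,
                    antibody_index=ab_index, placement=placement,
                )
            )
            if ab_index >= 0:
                gold_links.add((k, antibodies[ab_index].rrid))
            if placement == "legend":
                legend_sections.append(
                    Section(name=f"Figure {len(legend_sections) + 1}", paragraphs=(text,), is_legend=True)
                )
            else:
                layout = rng.random()
                if layout < 0.6:
                    para = " ".join([_filler(rng), text, _filler(rng)])
                elif layout < 0.75:
                    para = " ".join([text, _filler(rng)])
                elif layout < 0.9:
                    para = " ".join([_filler(rng), text])
                else:
                    para = text
                body_paragraphs.append(para)

        sections = [
            Section(name="Materials and Methods", paragraphs=tuple(mm_paragraphs)),
        ]
        if body_paragraphs:
            sections.append(Section(name="Results", paragraphs=tuple(body_paragraphs)))
        sections.extend(legend_sections)
        articles.append(
            GoldArticle(
                document=Document(doc_id=doc_id, sections=tuple(sections)),
                antibodies=antibodies,
                gold_spec=gold_spec,
                gold_rrid=gold_rrid,
                gold_links=gold_links,
            )
        )
    return articles


def _rrid_sentence(rng: np.random.Generator, ab: Antibody) -> str:
    tmpl = RRID_TEMPLATES[rng.integers(0, len(RRID_TEMPLATES))]
    return tmpl.format(
        target=ab.target, clone=ab.clone, cat=ab.catalog, rrid=ab.rrid, vendor=ab.vendor
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_article(article: GoldArticle, format: str = "plain") -> str:
    """Serialise a gold article to plain text or minimal JATS XML.

    Re-parsing the rendered output recovers all planted snippets (round-trip
    property asserted in the test suite).
    """
    doc = article.document
    if format == "plain":
        return "\n\n".join(p for _, _, p in doc.iter_paragraphs()) + "\n"
    if format != "jats":
        raise ValueError(f"unknown format {format!r}")
    parts = [
        "<article>",
        "<front><article-meta>"
        f"<article-id>{escape(doc.doc_id)}</article-id>"
        "</article-meta></front>",
        "<body>",
    ]
    fig_no = 0
    for sec in doc.sections:
        if sec.is_legend:
            fig_no += 1
            parts.append(
                f"<fig id=\"f{fig_no}\"><label>{escape(sec.name)}</label><caption>"
                + "".join(f"<p>{escape(p)}</p>" for p in sec.paragraphs)
                + "</caption></fig>"
            )
        else:
            parts.append(
                f"<sec><title>{escape(sec.name)}</title>"
                + "".join(f"<p>{escape(p)}</p>" for p in sec.paragraphs)
                + "</sec>"
            )
    parts.append("</body></article>")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


@dataclass
class DatasetBundle:
    """Model-ready datasets derived from a gold corpus.

    ``spec_examples`` are (doc_id, text, aspect, label) rows for the
    classifier; ``pairs`` enumerate every within-article (specificity snippet,
    RRID snippet) combination labeled yes iff linked in gold; ``joint_gold``
    carries (pair_id, link, class) triples for the workflow evaluation.
    """

    spec_examples: list[tuple[str, str, str, str]]
    pairs: list[SnippetPair]
    pair_ids: list[tuple[str, int, str]]
    joint_gold: list[tuple[tuple[str, int, str], str, str]]

    @property
    def yes_rate(self) -> float:
        if not self.pairs:
            return 0.0
        return sum(1 for p in self.pairs if p.label == "yes") / len(self.pairs)

    def to_aspect_instances(
        self, tokenizer: HashTokenizer | None = None, max_len: int = 256
    ) -> list[AspectInstance]:
        tok = tokenizer or HashTokenizer()
        return [
            build_input(text, aspect, tok, max_len=max_len, label=label)
            for _doc, text, aspect, label in self.spec_examples
        ]


def corpus_to_datasets(corpus: Sequence[GoldArticle]) -> DatasetBundle:
    """Run extraction over a gold corpus and attach gold labels.

    Specificity snippets are matched back to planted statements by their centre
    sentence; the extracted window text (with its surrounding filler sentences)
    is what enters the datasets, as in the real pipeline.
    """
    spec_examples: list[tuple[str, str, str, str]] = []
    pairs: list[SnippetPair] = []
    pair_ids: list[tuple[str, int, str]] = []
    joint_gold: list[tuple[tuple[str, int, str], str, str]] = []
    for art in corpus:
        snippets = filter_antibody_snippets(extract_spec_snippets(art.document))
        by_center = {st.text: (k, st) for k, st in enumerate(art.gold_spec)}
        rrid_snips = {sn.rrid: sn.text for sn in extract_rrid_snippets(art.document)}
        for sn in snippets:
            hit = by_center.get(sn.center_sentence)
            if hit is None:
                continue
            k, st = hit
            mentions = find_antibody_mentions(sn.text)
            aspect = mentions[0] if mentions else "antibody"
            spec_examples.append((art.doc_id, sn.text, aspect, st.label))
            for ab in art.antibodies:
                rtext = rrid_snips.get(ab.rrid)
                if rtext is None:
                    continue
                linked = (k, ab.rrid) in art.gold_links
                pid = (art.doc_id, k, ab.rrid)
                pairs.append(
                    SnippetPair(
                        spec_text=sn.text,
                        rrid_text=rtext,
                        rrid=ab.rrid,
                        label="yes" if linked else "no",
                    )
                )
                pair_ids.append(pid)
                joint_gold.append((pid, "yes" if linked else "no", st.label))
    return DatasetBundle(
        spec_examples=spec_examples,
        pairs=pairs,
        pair_ids=pair_ids,
        joint_gold=joint_gold,
    )
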