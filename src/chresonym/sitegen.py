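"""Static-site rendering of the cross-referenced dataset.

The whole site is regenerated on every run: two name indices plus one
page per specific name, compound name, publication, and species.  Every
cross-link between entries becomes a relative hyperlink, and output is
byte-identical across runs on identical input so builds are diffable.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass
from html.parser import HTMLParser
from pathlib import Path
from typing import Union

from jinja2 import Environment, PackageLoader, select_autoescape

from .crossref import CrossReference

__all__ = [
    "SiteBuild",
    "PageCollisionError",
    "generate_site",
    "check_links",
    "specific_page_name",
    "binomial_page_name",
]


class PageCollisionError(RuntimeError):
    """Two entries mapped to the same output file."""


@dataclass(frozen=True)
class PageRecord:
    path: str        # site-relative, forward slashes
    kind: str        # specific | binomial | publication | species | index
    source_key: str


@dataclass
class SiteBuild:
    outdir: Path
    manifest: list[PageRecord]


def _slug(text: str) -> str:
    joined = "_".join(text.split())
    return urllib.parse.quote(joined, safe="_.-")


def specific_page_name(epithet: str) -> str:
    return f"sn_{_slug(epithet)}.html"


def binomial_page_name(name: str) -> str:
    return f"{_slug(name)}.html"


def _environment() -> Environment:
    env = Environment(
        loader=PackageLoader("chresonym", "templates"),
        autoescape=select_autoescape(["html"]),
        keep_trailing_newline=True,
        trim_blocks=True,
        lstrip_blocks=True,
    )
    return env


def generate_site(xref: CrossReference, outdir: Union[str, Path]) -> SiteBuild:
    """Render every page; returns the manifest of emitted files."""
    outdir = Path(outdir)
    env = _environment()
    manifest: list[PageRecord] = []
    planned: dict[str, str] = {}

    def plan(path: str, kind: str, key: str) -> None:
        if path in planned:
            raise PageCollisionError(
                f"{path} generated by both {planned[path]!r} and {key!r}"
            )
        planned[path] = key
        manifest.append(PageRecord(path, kind, key))

    binomial_pages = {e.key: binomial_page_name(e.name) for e in xref.binomial_index}

    def make_links(current_dir: str) -> dict:
        def rel(target_dir: str, fname: str) -> str:
            return fname if target_dir == current_dir else f"../{target_dir}/{fname}"

        return {
            "specific": lambda ep: rel("names", specific_page_name(ep)),
            "binomial": lambda name: rel(
                "names", binomial_pages.get(name.lower(), binomial_page_name(name))
            ),
            "publication": lambda key: rel("references", f"{_slug(key)}.html"),
            "species": lambda sid: rel("species", f"{_slug(sid)}.html"),
        }

    species_by_id = {e.species.species_id: e.species for e in xref.species}

    def species_label(sid: str) -> str:
        sp = species_by_id.get(sid)
        return sp.binomial if sp else sid

    pages: list[tuple[str, str, str, str, dict]] = []  # path, kind, key, template, ctx

    pages.append((
        "names/index_specific.html", "index", "specific-index", "index_specific.html",
        {"entries": xref.specific_index},
    ))
    pages.append((
        "names/index_binomial.html", "index", "binomial-index", "index_binomial.html",
        {"entries": xref.binomial_index},
    ))
    for entry in xref.specific_index:
        pages.append((
            f"names/{specific_page_name(entry.epithet)}", "specific",
            entry.epithet, "specific_name.html",
            {"entry": entry},
        ))
    for entry in xref.binomial_index:
        pages.append((
            f"names/{binomial_page_name(entry.name)}", "binomial",
            entry.key, "binomial_name.html",
            {"entry": entry},
        ))
    for entry in xref.publications:
        pages.append((
            f"references/{_slug(entry.publication.key)}.html", "publication",
            entry.publication.key, "publication.html",
            {"entry": entry},
        ))
    for entry in xref.species:
        pages.append((
            f"species/{_slug(entry.species.species_id)}.html", "species",
            entry.species.species_id, "species.html",
            {"entry": entry},
        ))

    for path, kind, key, template, ctx in pages:
        plan(path, kind, key)

    for path, kind, key, template, ctx in pages:
        target = outdir / Path(path)
        target.parent.mkdir(parents=True, exist_ok=True)
        current_dir = path.split("/", 1)[0]
        ctx = dict(ctx, links=make_links(current_dir), species_label=species_label)
        html = env.get_template(template).render(**ctx)
        target.write_text(html, encoding="utf-8")

    return SiteBuild(outdir=outdir, manifest=sorted(manifest, key=lambda p: p.path))


class _LinkCollector(HTMLParser):
    def __init__(self) -> None:
        super().__init__()
        self.links: list[str] = []

    def handle_starttag(self, tag, attrs):
        for attr, value in attrs:
            if attr in ("href", "src") and value:
                self.links.append(value)


def check_links(build: Union[SiteBuild, str, Path]) -> list[tuple[str, str]]:
    """Crawl emitted pages; return (page, link) pairs whose internal
    target file does not exist.  External links are ignored."""
    outdir = build.outdir if isinstance(build, SiteBuild) else Path(build)
    broken: list[tuple[str, str]] = []
    for page in sorted(outdir.rglob("*.html")):
        collector = _LinkCollector()
        collector.feed(page.read_text(encoding="utf-8"))
        for link in collector.links:
            parsed = urllib.parse.urlparse(link)
            if parsed.scheme or parsed.netloc:
                continue
            # emitted file names keep their percent-encoding, so the raw
            # path component is the on-disk name
            path_part = parsed.path
            if not path_part:
                continue  # pure fragment
            target = (page.parent / path_part).resolve()
            if not target.exists():
                broken.append((str(page.relative_to(outdir)), link))
    return broken
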