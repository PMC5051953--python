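"""Embedded relational store for citation records.

The schema mirrors the table and column names of classic MEDLINE-to-SQL
loaders (``tbl_medline_citation``, ``tbl_medline_journal_info.medline_ta``,
``tbl_mesh_heading.descriptor_name``, ``fk_pmid`` foreign keys) so that the
well-known "journals by MeSH descriptor" aggregate translates verbatim:

    SELECT mj.medline_ta, count(DISTINCT mj.fk_pmid)
    FROM tbl_medline_journal_info mj
    JOIN tbl_mesh_heading msh ON mj.fk_pmid = msh.fk_pmid
    WHERE msh.descriptor_name = 'Leukemia'
    GROUP BY mj.medline_ta ORDER BY 2 DESC;

The engine is SQLite, so a store is a single file (or in-memory database)
and needs no running service.  Loading is idempotent and partition-order
invariant: a PMID is the primary key, re-inserting replaces, and deletion
markers remove.
"""

from __future__ import annotations

import hashlib
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .pubmed_xml import Citation, DeletionMarker, MeshHeading

__all__ = ["Store", "LoadReport"]

_SCHEMA = """
PRAGMA foreign_keys = ON;

CREATE TABLE IF NOT EXISTS tbl_medline_citation (
    pmid          INTEGER PRIMARY KEY,
    article_title TEXT NOT NULL,
    pub_year      INTEGER
);

CREATE TABLE IF NOT EXISTS tbl_abstract (
    fk_pmid       INTEGER NOT NULL REFERENCES tbl_medline_citation(pmid)
                  ON DELETE CASCADE,
    abstract_text TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS tbl_medline_journal_info (
    fk_pmid    INTEGER NOT NULL REFERENCES tbl_medline_citation(pmid)
               ON DELETE CASCADE,
    medline_ta TEXT,
    country    TEXT
);

CREATE TABLE IF NOT EXISTS tbl_mesh_heading (
    mesh_id         INTEGER PRIMARY KEY AUTOINCREMENT,
    fk_pmid         INTEGER NOT NULL REFERENCES tbl_medline_citation(pmid)
                    ON DELETE CASCADE,
    descriptor_name TEXT NOT NULL,
    major_topic     INTEGER NOT NULL DEFAULT 0
);

CREATE TABLE IF NOT EXISTS tbl_mesh_qualifier (
    fk_mesh_heading INTEGER NOT NULL REFERENCES tbl_mesh_heading(mesh_id)
                    ON DELETE CASCADE,
    qualifier_name  TEXT NOT NULL,
    position        INTEGER NOT NULL
);

CREATE TABLE IF NOT EXISTS tbl_keyword (
    fk_pmid INTEGER NOT NULL REFERENCES tbl_medline_citation(pmid)
            ON DELETE CASCADE,
    keyword TEXT NOT NULL,
    position INTEGER NOT NULL
);

CREATE TABLE IF NOT EXISTS tbl_chemical (
    fk_pmid           INTEGER NOT NULL REFERENCES tbl_medline_citation(pmid)
                      ON DELETE CASCADE,
    substance_name    TEXT NOT NULL,
    position          INTEGER NOT NULL
);

CREATE TABLE IF NOT EXISTS tbl_author (
    fk_pmid  INTEGER NOT NULL REFERENCES tbl_medline_citation(pmid)
             ON DELETE CASCADE,
    name     TEXT NOT NULL,
    position INTEGER NOT NULL
);

CREATE INDEX IF NOT EXISTS idx_mesh_descriptor
    ON tbl_mesh_heading(descriptor_name);
CREATE INDEX IF NOT EXISTS idx_journal_fk ON tbl_medline_journal_info(fk_pmid);
"""

_GROUP_FIELD_SQL = {
    "journal_ta": ("tbl_medline_journal_info", "medline_ta"),
    "country": ("tbl_medline_journal_info", "country"),
    "author": ("tbl_author", "name"),
}


@dataclass(frozen=True)
class LoadReport:
    """Counts from one :meth:`Store.load` call."""

    inserted: int
    replaced: int
    deleted: int


class Store:
    """A single-file relational store of citation records.

    Parameters
    ----------
    path
        SQLite database file, or ``":memory:"`` for an ephemeral store.
    """

    def __init__(self, path: str | Path = ":memory:") -> None:
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc_info) -> None:
        self.close()

    # -- loading -----------------------------------------------------------

    def load(self, records: Iterable[Citation | DeletionMarker]) -> LoadReport:
        """Load citations (and deletion markers) into the store.

        Within the batch, the last occurrence of a PMID wins, matching
        PubMed's update-file semantics.  Re-loading the same batch is a
        no-op on the final state, and splitting a batch of distinct PMIDs
        into partitions loaded in any order yields the same final store.
        """
        inserted = replaced = deleted = 0
        cur = self._conn.cursor()
        cur.execute("PRAGMA foreign_keys = ON")
        for record in records:
            if isinstance(record, DeletionMarker):
                cur.execute(
                    "DELETE FROM tbl_medline_citation WHERE pmid = ?", (record.pmid,)
                )
                deleted += cur.rowcount
                continue
            exists = cur.execute(
                "SELECT 1 FROM tbl_medline_citation WHERE pmid = ?", (record.pmid,)
            ).fetchone()
            if exists:
                cur.execute(
                    "DELETE FROM tbl_medline_citation WHERE pmid = ?", (record.pmid,)
                )
                replaced += 1
            else:
                inserted += 1
            self._insert(cur, record)
        self._conn.commit()
        return LoadReport(inserted=inserted, replaced=replaced, deleted=deleted)

    def _insert(self, cur: sqlite3.Cursor, c: Citation) -> None:
        cur.execute(
            "INSERT INTO tbl_medline_citation (pmid, article_title, pub_year)"
            " VALUES (?, ?, ?)",
            (c.pmid, c.title, c.pub_year),
        )
        if c.abstract is not None:
            cur.execute(
                "INSERT INTO tbl_abstract (fk_pmid, abstract_text) VALUES (?, ?)",
                (c.pmid, c.abstract),
            )
        if c.journal_ta is not None or c.country is not None:
            cur.execute(
                "INSERT INTO tbl_medline_journal_info (fk_pmid, medline_ta, country)"
                " VALUES (?, ?, ?)",
                (c.pmid, c.journal_ta, c.country),
            )
        for heading in c.mesh_headings:
            cur.execute(
                "INSERT INTO tbl_mesh_heading (fk_pmid, descriptor_name, major_topic)"
                " VALUES (?, ?, ?)",
                (c.pmid, heading.descriptor_name, int(heading.major_topic)),
            )
            mesh_id = cur.lastrowid
            for i, qualifier in enumerate(heading.qualifiers):
                cur.execute(
                    "INSERT INTO tbl_mesh_qualifier"
                    " (fk_mesh_heading, qualifier_name, position) VALUES (?, ?, ?)",
                    (mesh_id, qualifier, i),
                )
        for i, keyword in enumerate(c.keywords):
            cur.execute(
                "INSERT INTO tbl_keyword (fk_pmid, keyword, position) VALUES (?, ?, ?)",
                (c.pmid, keyword, i),
            )
        for i, substance in enumerate(c.chemicals):
            cur.execute(
                "INSERT INTO tbl_chemical (fk_pmid, substance_name, position)"
                " VALUES (?, ?, ?)",
                (c.pmid, substance, i),
            )
        for i, name in enumerate(c.authors):
            cur.execute(
                "INSERT INTO tbl_author (fk_pmid, name, position) VALUES (?, ?, ?)",
                (c.pmid, name, i),
            )

    # -- retrieval ---------------------------------------------------------

    def pmids(self) -> list[int]:
        rows = self._conn.execute(
            "SELECT pmid FROM tbl_medline_citation ORDER BY pmid"
        ).fetchall()
        return [r[0] for r in rows]

    def __len__(self) -> int:
        return self._conn.execute(
            "SELECT count(*) FROM tbl_medline_citation"
        ).fetchone()[0]

    def __contains__(self, pmid: int) -> bool:
        return (
            self._conn.execute(
                "SELECT 1 FROM tbl_medline_citation WHERE pmid = ?", (pmid,)
            ).fetchone()
            is not None
        )

    def get(self, pmid: int) -> Citation | None:
        """Reassemble the full Citation for one PMID, or None if absent."""
        row = self._conn.execute(
            "SELECT pmid, article_title, pub_year FROM tbl_medline_citation"
            " WHERE pmid = ?",
            (pmid,),
        ).fetchone()
        if row is None:
            return None
        abstract_row = self._conn.execute(
            "SELECT abstract_text FROM tbl_abstract WHERE fk_pmid = ?", (pmid,)
        ).fetchone()
        journal_row = self._conn.execute(
            "SELECT medline_ta, country FROM tbl_medline_journal_info"
            " WHERE fk_pmid = ?",
            (pmid,),
        ).fetchone()
        mesh = []
        for mesh_id, descriptor, major in self._conn.execute(
            "SELECT mesh_id, descriptor_name, major_topic FROM tbl_mesh_heading"
            " WHERE fk_pmid = ? ORDER BY mesh_id",
            (pmid,),
        ):
            qualifiers = tuple(
                q[0]
                for q in self._conn.execute(
                    "SELECT qualifier_name FROM tbl_mesh_qualifier"
                    " WHERE fk_mesh_heading = ? ORDER BY position",
                    (mesh_id,),
                )
            )
            mesh.append(MeshHeading(descriptor, qualifiers, bool(major)))
        keywords = tuple(
            r[0]
            for r in self._conn.execute(
                "SELECT keyword FROM tbl_keyword WHERE fk_pmid = ? ORDER BY position",
                (pmid,),
            )
        )
        chemicals = tuple(
            r[0]
            for r in self._conn.execute(
                "SELECT substance_name FROM tbl_chemical WHERE fk_pmid = ?"
                " ORDER BY position",
                (pmid,),
            )
        )
        authors = tuple(
            r[0]
            for r in self._conn.execute(
                "SELECT name FROM tbl_author WHERE fk_pmid = ? ORDER BY position",
                (pmid,),
            )
        )
        return Citation(
            pmid=row[0],
            title=row[1],
            abstract=abstract_row[0] if abstract_row else None,
            journal_ta=journal_row[0] if journal_row else None,
            country=journal_row[1] if journal_row else None,
            pub_year=row[2],
            mesh_headings=tuple(mesh),
            keywords=keywords,
            chemicals=chemicals,
            authors=authors,
        )

    def citations(self) -> Iterator[Citation]:
        """Iterate all citations in PMID order."""
        for pmid in self.pmids():
            citation = self.get(pmid)
            assert citation is not None
            yield citation

    # -- aggregate queries -------------------------------------------------

    def journals_by_descriptor(
        self, descriptor: str, limit: int = 10
    ) -> list[tuple[str, int]]:
        """Journals ranked by distinct-PMID count of one MeSH descriptor.

        Matching on ``descriptor_name`` is exact and case-sensitive (SQL
        equality).  Ties are broken by journal title abbreviation ascending.
        An unknown descriptor yields an empty list.
        """
        if limit < 1:
            raise ValueError(f"limit must be >= 1, got {limit}")
        rows = self._conn.execute(
            """
            SELECT mj.medline_ta, count(DISTINCT mj.fk_pmid) AS num_of_publications
            FROM tbl_medline_journal_info mj
            JOIN tbl_mesh_heading msh ON mj.fk_pmid = msh.fk_pmid
            WHERE msh.descriptor_name = ? AND mj.medline_ta IS NOT NULL
            GROUP BY mj.medline_ta
            ORDER BY num_of_publications DESC, mj.medline_ta ASC
            LIMIT ?
            """,
            (descriptor, limit),
        ).fetchall()
        return [(r[0], r[1]) for r in rows]

    def years_of(
        self, pmids: Iterable[int]
    ) -> tuple[dict[int, int], set[int]]:
        """Publication-year histogram for a PMID set.

        Returns ``(year -> count, missing)`` where ``missing`` holds PMIDs
        that are absent from the store or lack a publication year.
        """
        pmids = set(pmids)
        years: dict[int, int] = {}
        missing: set[int] = set()
        for pmid in pmids:
            row = self._conn.execute(
                "SELECT pub_year FROM tbl_medline_citation WHERE pmid = ?", (pmid,)
            ).fetchone()
            if row is None or row[0] is None:
                missing.add(pmid)
            else:
                years[row[0]] = years.get(row[0], 0) + 1
        return years, missing

    def group_count(
        self, pmids: Iterable[int], field: str
    ) -> list[tuple[str, int]]:
        """Distinct-PMID counts grouped by journal, country, or author.

        Ranked descending by count, ties by grouped value ascending.
        """
        if field not in _GROUP_FIELD_SQL:
            raise ValueError(
                f"field must be one of {sorted(_GROUP_FIELD_SQL)}, got {field!r}"
            )
        pmids = sorted(set(pmids))
        if not pmids:
            return []
        table, column = _GROUP_FIELD_SQL[field]
        placeholders = ",".join("?" * len(pmids))
        rows = self._conn.execute(
            f"""
            SELECT {column}, count(DISTINCT fk_pmid) AS n
            FROM {table}
            WHERE fk_pmid IN ({placeholders}) AND {column} IS NOT NULL
            GROUP BY {column}
            ORDER BY n DESC, {column} ASC
            """,
            pmids,
        ).fetchall()
        return [(r[0], r[1]) for r in rows]

    # -- escape hatch and state -------------------------------------------

    def sql(self, query: str, params: Sequence | Mapping = ()) -> list[tuple]:
        """Run a raw read-only SQL query against the store schema."""
        return self._conn.execute(query, params).fetchall()

    def state_dump(self) -> bytes:
        """Canonical serialization of the full logical store state.

        Rows of every table are sorted by content, so two stores hold
        identical data if and only if their dumps are byte-identical —
        regardless of insertion order or on-disk page layout.  The
        surrogate ``mesh_id`` key is normalised away.
        """
        parts: list[str] = []
        tables = (
            ("tbl_medline_citation", "pmid, article_title, pub_year"),
            ("tbl_abstract", "fk_pmid, abstract_text"),
            ("tbl_medline_journal_info", "fk_pmid, medline_ta, country"),
            ("tbl_keyword", "fk_pmid, keyword, position"),
            ("tbl_chemical", "fk_pmid, substance_name, position"),
            ("tbl_author", "fk_pmid, name, position"),
        )
        for table, cols in tables:
            rows = self._conn.execute(
                f"SELECT {cols} FROM {table} ORDER BY {cols}"
            ).fetchall()
            parts.append(f"## {table}")
            parts.extend(repr(row) for row in rows)
        mesh_rows = self._conn.execute(
            """
            SELECT m.fk_pmid, m.descriptor_name, m.major_topic,
                   group_concat(q.qualifier_name, '|')
            FROM tbl_mesh_heading m
            LEFT JOIN tbl_mesh_qualifier q ON q.fk_mesh_heading = m.mesh_id
            GROUP BY m.mesh_id
            ORDER BY m.fk_pmid, m.descriptor_name, m.major_topic, 4
            """
        ).fetchall()
        parts.append("## tbl_mesh_heading")
        parts.extend(repr(row) for row in mesh_rows)
        return "\n".join(parts).encode("utf-8")

    def state_digest(self) -> str:
        """SHA-256 of :meth:`state_dump`."""
        return hashlib.sha256(self.state_dump()).hexdigest()
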