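"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithmic machinery (networkx
condensation, the fixpoint loop in seed_scope, the curation fixpoint): seeds
are found by hand-rolled transitive closure, scope by naive repeated
re-scanning, coding density by a per-position bitmap, and the joint
disconnection rule by exhaustive exploration of one-at-a-time removal orders.
"""

from __future__ import annotations

from itertools import chain


def closure_seed_members(nodes: set[str], edges: set[tuple[str, str]]) -> frozenset[str]:
    """A node is a seed member iff every node that reaches it is also
    reached by it (i.e. nothing strictly upstream exists)."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)

    def reach(start: str) -> set[str]:
        seen = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return seen

    r = {n: reach(n) for n in nodes}
    return frozenset(
        n for n in nodes if all(n not in r[u] or u in r[n] for u in nodes if u != n)
    )


def rescan_scope(reactions, sources: frozenset[str]) -> frozenset[str]:
    """Naive repeated-scan network expansion with AND firing semantics.
    ``reactions`` is an iterable of objects with .substrates/.products
    (irreversible view) or (subs, prods) tuples."""
    directed = []
    for r in reactions:
        if isinstance(r, tuple):
            directed.append(r)
        else:
            directed.append((r.substrates, r.products))
            if getattr(r, "reversible", False):
                directed.append((r.products, r.substrates))
    out = set(sources)
    changed = True
    while changed:
        changed = False
        for subs, prods in directed:
            if all(s in out for s in subs) and not set(prods) <= out:
                out.update(prods)
                changed = True
    return frozenset(out)


def bitmap_coverage(intervals, genome_length: int) -> int:
    """Positions (1-based inclusive) covered by at least one interval."""
    covered = bytearray(genome_length + 1)
    for s, e in intervals:
        for i in range(s, e + 1):
            covered[i] = 1
    return sum(covered)


def all_disconnection_outcomes(rxns_a, rxns_b, sources: frozenset[str]):
    """Explore every one-at-a-time removal order of the joint disconnection
    rule; returns the set of reachable terminal states, each a pair of
    frozensets of retained reaction ids. Feasible for <= ~6 reactions total."""

    def products(rxns):
        return set(chain.from_iterable(r.products for r in rxns))

    def removable(state):
        ra, rb = state
        prod_a = products(ra)
        prod_b = products(rb)
        moves = []
        for side, (own, own_prod, partner_prod) in enumerate(
            ((ra, prod_a, prod_b), (rb, prod_b, prod_a))
        ):
            partner_pool = partner_prod | sources
            for r in own:
                if any(s in sources or s in own_prod for s in r.substrates):
                    continue
                mets = set(r.substrates) | set(r.products)
                if mets & partner_pool:
                    continue  # partner safeguard retains it
                moves.append((side, r))
        return moves

    terminals = set()
    seen_states = set()
    start = (frozenset(rxns_a), frozenset(rxns_b))
    stack = [start]
    while stack:
        state = stack.pop()
        key = (frozenset(r.id for r in state[0]), frozenset(r.id for r in state[1]))
        if key in seen_states:
            continue
        seen_states.add(key)
        moves = removable(state)
        if not moves:
            terminals.add(key)
            continue
        for side, r in moves:
            ra, rb = state
            if side == 0:
                stack.append((ra - {r}, rb))
            else:
                stack.append((ra, rb - {r}))
    return terminals
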