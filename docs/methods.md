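# Methods

## Threat model and protocol

The protocol links datasets held by $n \ge 2$ institutions through a
computation server, with one designated client (possibly an institution)
receiving the integrated result. All parties are assumed
*honest-but-curious*: they follow the protocol but may inspect everything
they receive. Under that model:

- the server sees only probabilistic ciphertexts, homomorphic sums,
  partial decryptions and sealed payloads — it holds neither the joint
  decryption key nor the Bloom salt, so it can neither decrypt nor mount a
  dictionary attack on filter positions;
- each institution learns only which of **its own** keys are held by all
  participants (the defining leakage of an n-way private set
  intersection), never another party's non-common keys;
- the client receives payload rows grouped by an anonymous link id (an
  HMAC of the compressed key under an institutions-only secret) and no key
  material.

Malicious-adversary robustness, side channels and network fault tolerance
are out of scope. All roles run in one process; the message transcript
(JSON-lines with byte counts) is the unit of analysis, and a field
deployment would move the same messages over sockets without changing
their content.

### Cryptosystem

Lifted (exponential) ElGamal over a Schnorr group. Messages are Bloom
counts bounded by $n$, so decoding the discrete log is an exact table
lookup over $\{g^0, \dots, g^n\}$. The joint secret key is an additive
sharing $x = \sum_i x_i \bmod q$: key generation is simulated centrally
and shares distributed in-process (no distributed key-generation
ceremony), but no party ever holds $x$, and decryption requires every
share — dropping any single partial decryption leaves $g^m h'\,(h' \ne 1)$,
which decodes to the wrong value or not at all.

Parameter modes:

| mode | group | randomness |
|---|---|---|
| `production` | 2048-bit safe prime (RFC 3526 group 14), $g=4$, $q=(p-1)/2$ | system CSPRNG |
| `test` | 61-bit safe prime $p = 1346898466362022187$ (plus a $q=101$ toy group for worked examples) | seedable `random.Random` |

Test mode is deliberately insecure; its point is fast, bit-reproducible
transcripts. The mode is recorded in every transcript header, and seeded
randomness is rejected outside test mode.

Payload rows travelling to the client are sealed with an ElGamal KEM in
the same group plus a SHA-256 counter-mode stream: transport protection
from the server, not part of the homomorphic layer.

### Bloom encoding

All institutions in a session share the filter geometry and a random salt
agreed out of band. Capacity is the largest declared set size; $m =
\lceil -n_{\text{cap}} \ln p_f / (\ln 2)^2 \rceil$ bits and $k = m/n_{\text{cap}}
\ln 2$ hashes target a per-key false-positive probability $p_f \le
10^{-9}$, so Bloom saturation is negligible next to real key collisions
and the protocol output equals the plaintext set intersection in practice
(property-tested over hundreds of randomized sessions). Positions are $k$
independent salted SHA-256 hashes; an arithmetic-progression ("double
hashing") scheme was measured to exceed the closed-form false-positive
rate at small $m$ because probe and insert positions share the
progression structure, and was rejected. Encoding is per-position bits
{0,1}; no counting or similarity filters — matching is exact by design.

## Matching keys

Canonicalization is deliberately thin: Unicode NFKC (folding full-width
digits and half-width kana), whitespace strip, birth dates to ISO-8601,
sex to {M, F, U}. Missing values canonicalize to the empty string, so two
records both lacking a field still agree on it. Keys are SHA-256 digests
of the canonical values of the chosen attribute combination, joined in a
fixed attribute order with a U+001F separator — equal keys iff all
combination attributes agree after canonicalization. The default
attribute set is family/first name in kanji and kana, birth date and sex
(57 combinations of size ≥ 2); sex is dropped for all-female screening
populations (26 combinations). Address is supported as an optional
seventh attribute but excluded from the default enumeration, since
free-text addresses are the least standardized field. Phonetic or
edit-distance matching is intentionally absent: the experiment measures
what exact matching achieves.

## Synthetic data

The generator emulates what the matching experiment needs and no more:

- internally consistent Japanese pseudo-identities (the kana field is a
  true reading of the kanji field, drawn jointly from a small editable
  lexicon), valid birth dates, structured addresses;
- a planted common subset present in both tables, with the registry copy
  perturbed and the screening copy clean;
- a ground-truth link table fixed before error injection and invariant
  under it (independent RNG streams per concern, so changing the error
  plan cannot reorder rows or alter the population).

Error operators follow the taxonomy a registry audit would use. Each
touches exactly its declared attribute fields and must change the
*canonical* value (a width-only change that NFKC undoes would not be an
error at matching time — the address-format operator therefore
restructures block numbering rather than just switching digit width).
Category semantics worth noting: IME conversion errors change kanji while
the reading stays correct; misreadings change kana while kanji is
untouched (using the lexicon's alternative readings where available, e.g.
裕子 read ひろこ for ゆうこ); name changes and aliases replace a whole
name coherently in both scripts; omission drops a name component from
both scripts.

The built-in plans reproduce two study conditions: a colorectal pair
(2000 screening / 17,866 registry rows, 60 common, 51 perturbed of which
25 on ≥ 2 key attributes) and an all-female breast pair (1048 / 29,949,
62 common, 36 perturbed, 14 multi-key). These error rates (85% and 59% of
the common subset) are deliberate worst cases, far above the <10–15%
reported for real registries. Plans are *marginals*, hit exactly by a
deterministic allocator: inherently two-attribute categories seed
multi-key records, compatible pairs of single-attribute errors fill the
rest, and when the instance budget cannot afford a pair, one name error
is applied to both name components (one table entry, two attributes — the
breast plan needs exactly one such promotion). Extras stack onto existing
multi-key records, never repeating a table row on one record. An audit
pass recomputes every marginal from the canonical before/after diff and
fails loudly on any deviation, including a vacuous operator.

What the generator does **not** model: realistic name/address frequency
distributions (the lexicons are small), scanning/OCR artifacts, duplicate
registrations of one person, or the correlation structure of real entry
errors. Passing tests therefore demonstrate protocol correctness and the
*mechanics* of accuracy degradation under errors, not the matching
sensitivity any particular real registry would achieve.

## Evaluation

The screening dataset is the reference population. Per screening record:
linked to its true counterpart → TP; counterpart exists but unlinked →
FN; no counterpart but linked → FP; no counterpart, unlinked → TN. A
record linked both to its counterpart and to a stranger counts one TP
*and* one FP, so multi-matches are never absorbed silently; groups retain
per-source multiplicity so duplicate-key links stay visible. Matching
sensitivity $= 100\,\mathrm{TP}/(\mathrm{TP}+\mathrm{FN})$ and
specificity $= 100\,\mathrm{TN}/(\mathrm{TN}+\mathrm{FP})$ are printed to
2 decimals, rounding half-up. Sweeps support a plaintext hash-join fast
path and the full protocol path; their exact agreement on identical
inputs is the core correctness test.

## Accuracy propagation

The closed forms in the README assume linkage errors are independent of
the screen result (non-differential outcome misclassification) and
depend on rates only — cohort size cancels, which the tests assert. Each
formula is validated against an independent expected-count 2×2×2
cross-tabulation at $N = 10^7$ over randomized scenarios (agreement to
4 decimals before rounding). Identity cells (matching sensitivity or
specificity exactly 100%) are flagged and rendered "NA" in the scenario
grid, except in the two rows carrying experimentally observed matching
accuracies, where values are printed. Percentages round half-up to
2 decimals (1 decimal for true PPV, following the conventional
presentation). For cohort and case-control designs the same
misclassification algebra is exposed directly: perfect matching
specificity leaves the risk ratio untouched (sensitivity scales both arms
equally), while imperfect specificity attenuates risk and odds ratios
toward the null.

## Numerical and size choices

- Discrete-log decoding: precomputed lookup table per decode bound;
  out-of-range quotients raise a decode error rather than returning a
  guess.
- Deterministic ordering everywhere ties could occur: attribute order in
  key digests, size-then-position order for combinations, sorted link ids
  in the integrated result.
- Test problem sizes: property tests run dozens of randomized sessions at
  up to 512 keys with test-mode crypto, and the scaled end-to-end run
  uses a 2^10-record pair — large enough to exercise filter sizing and
  multi-institution decoding while keeping the default suite near half a
  minute.
- Degenerate inputs fail loudly: zero prevalence, empty strata, summed
  Bloom counts above $n$, plans whose marginals are combinatorially
  infeasible.

## Known limitations

- Honest-but-curious only; no protection against a party submitting a
  malformed filter.
- The link id is pseudonymous, not anonymous in the formal sense: a
  client colluding with an institution can re-identify groups.
- Exact matching only; every perturbed key attribute in a combination is
  an unrecoverable miss, which is precisely the effect under study.
- The in-process transport reports message sizes, not wall-clock network
  behaviour; timing and resource benchmarks are environment-bound and
  out of scope.
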