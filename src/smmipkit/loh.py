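"""Loss-of-heterozygosity calling from heterozygous-site allele fractions.

In a pure tumor, loss of one allele drives the major allele fraction of a
heterozygous site to 1; diluted by normal cells at tumor purity rho, the
expected major VAF under LOH is 1/(2 - rho) (e.g. 0.77 at rho = 0.7).
Informative sites are known germline variants called in a heterozygous
state (5% <= VAF <= 95%); a locus with an average major VAF above 60% is
called LOH.  Samples with a low neoplastic-cell fraction (< 32%) get a
caveat flag, since their LOH signal may be diluted below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calling import VariantCall

HET_VAF_MIN = 0.05
HET_VAF_MAX = 0.95
MAJOR_VAF_THRESHOLD = 0.60
LOW_PURITY_CAVEAT = 0.32


@dataclass(frozen=True)
class InformativeSite:
    pos: int
    vaf: float
    source: str = "known_germline_snp"  # or confirmed_germline_variant

    def __post_init__(self):
        if not HET_VAF_MIN <= self.vaf <= HET_VAF_MAX:
            raise ValueError(
                f"site at {self.pos}: VAF {self.vaf} outside the heterozygous "
                f"window [{HET_VAF_MIN}, {HET_VAF_MAX}]"
            )

    @property
    def major_vaf(self) -> float:
        return max(self.vaf, 1.0 - self.vaf)


@dataclass
class LOHCall:
    locus: str
    n_sites: int
    mean_major_vaf: float | None
    status: str            # LOH | no_LOH | uninformative
    low_purity_caveat: bool = False


def select_informative(
    calls: list[VariantCall],
    locus: tuple[int, int] | None = None,
    require_pass: bool = True,
) -> list[InformativeSite]:
    """Known-germline calls in the heterozygous-state VAF window.

    ``locus`` restricts to a (start, end) interval; artifact-filtered calls
    are excluded unless ``require_pass`` is False (``low_depth`` never
    qualifies).
    """
    sites = []
    for c in calls:
        if c.origin != "known_germline":
            continue
        if locus is not None and not (locus[0] <= c.pos < locus[1]):
            continue
        if require_pass and not c.is_pass:
            continue
        if not require_pass and "low_depth" in c.filters:
            continue
        if HET_VAF_MIN <= c.vaf <= HET_VAF_MAX:
            sites.append(InformativeSite(pos=c.pos, vaf=c.vaf))
    return sites


def call_loh(
    sites: list[InformativeSite],
    locus: str = "locus",
    threshold: float = MAJOR_VAF_THRESHOLD,
    tumor_purity: float | None = None,
) -> LOHCall:
    """Average the major VAF over informative sites; > threshold means LOH.

    With zero sites the locus is uninformative.  When the sample's
    neoplastic-cell fraction is supplied and below 32%, the call carries a
    low-purity caveat regardless of status.
    """
    caveat = tumor_purity is not None and tumor_purity < LOW_PURITY_CAVEAT
    if not sites:
        return LOHCall(locus, 0, None, "uninformative", caveat)
    mean_major = sum(s.major_vaf for s in sites) / len(sites)
    status = "LOH" if mean_major > threshold else "no_LOH"
    return LOHCall(locus, len(sites), mean_major, status, caveat)


def write_loh_tsv(calls: list[LOHCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tn_sites\tmean_major_vaf\tstatus\tlow_purity_caveat\n")
        for c in calls:
            mv = "." if c.mean_major_vaf is None else f"{c.mean_major_vaf:.4f}"
            fh.write(f"{c.locus}\t{c.n_sites}\t{mv}\t{c.status}\t{int(c.low_purity_caveat)}\n")
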