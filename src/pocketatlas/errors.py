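"""Exception hierarchy.

Every failure mode that callers are expected to branch on gets its own
class; all inherit from :class:`PocketAtlasError` so blanket handling
remains possible.
"""


class PocketAtlasError(Exception):
    """Base class for all package-specific errors."""


# --- structure parsing / generation ---------------------------------------

class ParseError(PocketAtlasError):
    """The input file could not be parsed as PDB."""


class LigandNotFound(PocketAtlasError):
    """No non-water HETATM group matches the ligand selector."""


class AmbiguousLigand(PocketAtlasError):
    """The selector matches more than one HETATM group and carries no
    chain/residue-number disambiguator."""


class EmptyProtein(PocketAtlasError):
    """No protein residues remain after chain filtering."""


class GenerationError(PocketAtlasError):
    """Synthetic-complex constraints could not be satisfied within the
    bounded number of retries."""


# --- tessellation ----------------------------------------------------------

class DegenerateGeometry(PocketAtlasError):
    """The atomic point set is degenerate (coplanar/collinear) and the
    tessellation cannot be built; retry with distance-only fallback."""


class EmptyInterface(PocketAtlasError):
    """No protein residue is in contact with the ligand at the given
    truncation radius."""


# --- embedding -------------------------------------------------------------

class AlphabetError(PocketAtlasError):
    """Sequence contains a character outside the 20 standard amino-acid
    letters plus 'X', or is empty."""


class EmbedderUnavailable(PocketAtlasError):
    """The external protein-language-model adapter cannot load its model.
    Never silently replaced by the mock."""


class IndexMismatch(PocketAtlasError):
    """An interface residue index falls outside the embedding matrix;
    signals sequence/structure misalignment."""


class EmbedderMismatch(PocketAtlasError):
    """Pocket vectors from different embedders (or dimensions) were mixed."""


# --- metric ----------------------------------------------------------------

class DegenerateScale(PocketAtlasError):
    """All off-diagonal distances are equal; min-max normalization is
    undefined."""


class EmptyInput(PocketAtlasError):
    """An empty sequence was passed where a non-empty one is required."""


class ShapeError(PocketAtlasError):
    """Paired arrays have mismatched lengths or are too short."""


# --- clustering / atlas ----------------------------------------------------

class IdMismatch(PocketAtlasError):
    """Two objects that must share an id set do not."""


class EdgeNotFound(PocketAtlasError):
    """The requested edge is not present in the (remaining) tree."""


class DegenerateVariance(PocketAtlasError):
    """Spatial autocorrelation is undefined for constant values."""


class WeightError(PocketAtlasError):
    """Inverse-distance weights are undefined (zero off-diagonal cluster
    distance)."""


class FormatError(PocketAtlasError):
    """Unknown graph export format."""


# --- splits / druggability -------------------------------------------------

class EmptyTrain(PocketAtlasError):
    """A split operation left the training side empty."""


class EmptyTest(PocketAtlasError):
    """A split operation left the test side empty."""


class DegenerateLabels(PocketAtlasError):
    """Training data contains a single class only."""


class UndefinedAUC(PocketAtlasError):
    """ROC-AUC is undefined because the evaluated side has one class."""
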