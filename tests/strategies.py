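"""Hypothesis strategies over the parser-spec space."""

from hypothesis import strategies as st

from plateparse.spec_model import (
    AxisLabels,
    BlockRange,
    CellRef,
    ParserSpec,
    WellLayout,
)
from plateparse.wells import enumerate_wells


@st.composite
def block_at(draw, n_rows: int, n_cols: int, max_origin: int = 40) -> BlockRange:
    r0 = draw(st.integers(1, max_origin))
    c0 = draw(st.integers(1, max_origin))
    return BlockRange(CellRef(r0, c0), CellRef(r0 + n_rows - 1, c0 + n_cols - 1))


@st.composite
def parser_specs(draw) -> ParserSpec:
    """Structurally valid specs across format x type x readings x axis x wells."""
    data_format = draw(st.sampled_from(["horizontal", "vertical", "matrix"]))
    if data_format == "matrix":
        data_type = "single"
    else:
        data_type = draw(st.sampled_from(["single", "timecourse", "spectrum"]))
    axis_len = 1 if data_type == "single" else draw(st.integers(2, 12))

    num_readings = draw(st.integers(1, 4))
    reading_names = tuple(f"reading_{i + 1}" for i in range(num_readings))

    plate_rows = draw(st.integers(1, 16))
    plate_cols = draw(st.integers(1, 24))
    if data_format == "matrix" or draw(st.booleans()):
        wells = WellLayout(mode="plate", plate_rows=plate_rows, plate_cols=plate_cols)
        n_wells = plate_rows * plate_cols
    else:
        ids = enumerate_wells(plate_rows, plate_cols)[::2] or ["A1"]
        wells = WellLayout(mode="explicit", well_ids=tuple(ids))
        n_wells = len(ids)

    if data_format == "horizontal":
        shape = (axis_len, n_wells)
    elif data_format == "vertical":
        shape = (n_wells, axis_len)
    else:
        shape = (plate_rows, plate_cols)
    first_block = draw(block_at(*shape))

    stride = draw(st.none() | st.integers(1, 30))
    explicit_blocks = None
    if draw(st.booleans()):
        offsets = draw(
            st.lists(st.integers(0, 50), min_size=num_readings, max_size=num_readings)
        )
        explicit_blocks = tuple(
            first_block.shifted(d_rows=off) for off in offsets
        )

    axis = None
    if data_type != "single":
        mode = draw(st.sampled_from(["explicit", "from_grid", "uniform"]))
        if mode == "explicit":
            axis = AxisLabels(
                mode="explicit",
                values=tuple(
                    draw(
                        st.lists(
                            st.integers(0, 10_000),
                            min_size=axis_len,
                            max_size=axis_len,
                        )
                    )
                ),
            )
        elif mode == "from_grid":
            horizontal_ref = draw(st.booleans())
            ref_shape = (1, axis_len) if horizontal_ref else (axis_len, 1)
            axis = AxisLabels(mode="from_grid", ref=draw(block_at(*ref_shape)))
        else:
            axis = AxisLabels(
                mode="uniform",
                start=draw(st.integers(0, 1000)) * 1.0,
                step=draw(st.integers(1, 600)) * 1.0,
            )

    sentinels = draw(
        st.none()
        | st.lists(
            st.sampled_from(["", "NA", "OVRFLW", "OVER", "#SAT", "?"]),
            min_size=1,
            max_size=4,
            unique=True,
        )
    )
    kwargs = dict(
        data_format=data_format,
        data_type=data_type,
        first_block=first_block,
        num_readings=num_readings,
        reading_names=reading_names,
        block_stride=stride,
        explicit_blocks=explicit_blocks,
        wells=wells,
        axis=axis,
        dialect=draw(st.none() | st.sampled_from(["csv", "csv2", "tsv", "txt", "excel"])),
        sheet=draw(st.none() | st.integers(1, 5) | st.sampled_from(["Sheet1", "Data"])),
        delimiter=draw(st.none() | st.sampled_from([" ", "|"])),
    )
    if sentinels is not None:
        kwargs["sentinel_values"] = tuple(sentinels)
    return ParserSpec(**kwargs)
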