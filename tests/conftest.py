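import pytest

from firecarbon import (
    FuelTransect,
    PlotInventory,
    SoilSample,
    TreeRecord,
    UnderstoryRecord,
    default_constants,
    default_table,
)


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def constants():
    return default_constants()


def make_tree(dbh=30.0, species="PIPO", status="live", tag="T001",
              height=22.0, frame="main_plot", plot_id="U01-P01"):
    return TreeRecord(plot_id=plot_id, tag=tag, species=species, dbh=dbh,
                      height=height, status=status, sample_frame=frame)


def make_transect(plot_id="U01-P01", azimuth=0.0, c1=4, c10=6, c100=2,
                  cwd=(), litter=(2.0, 2.0), duff=(3.0, 3.0)):
    return FuelTransect(plot_id=plot_id, azimuth=azimuth, counts_1h=c1,
                        counts_10h=c10, counts_100h=c100,
                        cwd_diameters=list(cwd), litter_depths=litter,
                        duff_depths=duff)


def make_plot(year=2001, trees=None, understory=None, transects=None,
              soil=None, plot_id="U01-P01", unit_id="U01", treatment="Control"):
    return PlotInventory(
        plot_id=plot_id, unit_id=unit_id, treatment=treatment, year=year,
        trees=list(trees or []),
        understory=list(understory or []),
        transects=list(transects if transects is not None
                       else [make_transect(plot_id, 0.0), make_transect(plot_id, 180.0)]),
        soil=list(soil or []),
    )


@pytest.fixture
def simple_plot():
    trees = [
        make_tree(dbh=50.0, species="PIPO", tag="T001", height=32.0),
        make_tree(dbh=30.0, species="ABCO", tag="T002", height=24.0),
        make_tree(dbh=18.0, species="CADE", tag="T003", height=15.0),
        make_tree(dbh=5.0, species="ABCO", tag="T004", height=4.0, frame="subplot"),
        make_tree(dbh=40.0, species="PSME", tag="T005", height=28.0, status="snag"),
    ]
    understory = [
        UnderstoryRecord(plot_id="U01-P01", species="CEIN", cover_class="5to25",
                         growth_form="shrub"),
        UnderstoryRecord(plot_id="U01-P01", species="HERB", cover_class="lt5",
                         growth_form="herb"),
    ]
    soil = [SoilSample(plot_id="U01-P01", bulk_density=0.9, carbon_pct=5.0)]
    return make_plot(trees=trees, understory=understory, soil=soil)
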