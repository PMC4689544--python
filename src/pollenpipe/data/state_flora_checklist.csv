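species,species_listed,genus_listed,is_bryophyte
Melilotus officinalis,True,True,False
Sonchus arvensis,True,True,False
Anemone canadensis,True,True,False
Artemisia absinthium,True,True,False
Cirsium arvense,True,True,False
Brassica nigra,True,True,False
Brassica oleracea,False,True,False
Bassia scoparia,True,True,False
Helenium autumnale,True,True,False
Helianthus petiolaris,True,True,False
Raphanus sativus,True,True,False
Spartina pectinata,True,True,False
Zea mays,True,True,False
Brassica napus,False,True,False
Elaeagnus moorcroftii,True,True,False
Phalaris arundinacea,True,True,False
Cirsium vulgare,True,True,False
Cicuta maculata,True,True,False
Persicaria viscosa,False,True,False
Ratibida peduncularis,False,True,False
Sium suave,True,True,False
Brassica juncea,True,True,False
Bolboschoenus caldwellii,False,True,False
Lactuca serriola,True,True,False
Dalea purpurea,True,True,False
Convolvulus arvensis,True,True,False
Monarda fistulosa,True,True,False
Euphorbia esula,True,True,False
Brassica carinata,False,True,False
Heterotheca villosa,True,True,False
Actites megalocarpa,False,False,False
Chamerion angustifolium,True,True,False
Ceratodon purpureus,False,False,True
Populus deltoides,True,True,False
Helianthus praecox,False,True,False
Amorpha fruticosa,True,True,False
Arctium lappa,True,True,False
Imbribryum blandum,False,False,True
Lonicera pilosa,False,True,False
Viburnum prunifolium,False,True,False
Helianthus pauciflorus,True,True,False
Symphoricarpos occidentalis,True,True,False
Trifolium retusum,False,True,False
Lonicera japonica,False,True,False
Symphyotrichum novae-angliae,True,True,False
Funaria hygrometrica,False,False,True
Trifolium repens,True,True,False
Lactuca sibirica,False,True,False
Helianthus occidentalis,False,True,False
Eurybia divaricata,False,True,False
Pseudoroegneria tauri,False,True,False
Symphyotrichum cordifolium,False,True,False
Sinapis arvensis,True,True,False
Allium stellatum,True,True,False
Phleum pratense,True,True,False
Pleurozium schreberi,False,False,True
Elymus repens,True,True,False
Solidago houghtonii,False,True,False
Laportea canadensis,True,True,False
Panicum queenslandicum,False,True,False
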