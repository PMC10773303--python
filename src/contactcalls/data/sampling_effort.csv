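city,park,n_days,n_calls,n_nest_openings
Athens,Oluf Palme Playground,3,35,9
Athens,National Garden,4,287,49
Athens,Alsos Ilision,2,52,10
Athens,Gendarmerie School Park,3,86,99
Athens,Thissio Park,1,2,1
Barcelona,Parc de la Ciutadella,3,85,33
Barcelona,Jardins del Turo del Putxet,1,98,1
Barcelona,Jardins de Ghandi,1,2,4
Barcelona,Jardins de Josep Trueta,1,20,7
Barcelona,Parc Grande de Sant Marti,1,44,54
Barcelona,Jardins de la Maternitat,1,19,11
Bergamo,Faunistic Park Le Cornelle,2,456,26
Brussels,Parc de Forest,4,559,96
Brussels,Ten Reuken,2,19,
Brussels,Avenue Louise,1,6,7
Brussels,Tenenbosch Park,1,10,1
Brussels,Place Guy D'Arezzo,2,107,13
Legnago,Legnago,2,345,10
Madrid,Parque de el Ritero,1,13,
Madrid,Parque de Berlin,3,218,65
Madrid,Lago Casa del Campo,2,91,18
Madrid,Parque Azorin,2,141,55
Madrid,Parque Emperatriz Maria de Austria,1,45,
Madrid,Parque Infantil Portalegre,1,9,6
Madrid,Quintos de Molinos,1,10,2
Madrid,Parque Alfredo Kraus,1,5,10
Pavia,Oasi di Sant'Alessio,1,756,34
Verona,Parco Natura Viva,1,110,37
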