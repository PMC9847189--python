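# Default mapping from CNAE-style activity-code prefixes to food-retail
# subcategories.  Codes are matched by longest prefix; anything unmatched
# is counted as non_food.  Edit or replace this file to fit the coding
# scheme of your establishment registry.
#
# Macro classes are fixed by subcategory:
#   in_natura:      butchery, seafood, fruits_vegetables
#   ultraprocessed: street_vendor, bar, cafeteria, convenience, candy
#   mixed:          hypermarket_supermarket, food_store, mini_market,
#                   bakery, restaurant
code_prefixes:
  "47113": hypermarket_supermarket   # hiper/supermercados
  "47121": mini_market               # minimercados, mercearias e armazens
  "47211": bakery                    # padaria e confeitaria
  "47212": candy                     # doces, balas, bombons
  "47221": butchery                  # carnes (acougues)
  "47222": seafood                   # peixarias
  "47245": fruits_vegetables         # hortifrutigranjeiros
  "47296": food_store                # demais produtos alimenticios
  "47297": convenience               # lojas de conveniencia
  "56112": restaurant                # restaurantes e similares
  "56113": cafeteria                 # lanchonetes (snack bars)
  "56114": bar                       # bares e outros servicos de bebidas
  "56121": street_vendor             # servicos ambulantes de alimentacao

# Subcategories summed for the food-swamp count (> 4 establishments
# flags a swamp).  "Grocery stores" in the swamp definition is read as
# mini markets; override here if your registry distinguishes them.
swamp_subcategories:
  - convenience
  - cafeteria
  - mini_market
  - candy
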